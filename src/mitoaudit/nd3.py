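"""Detection of the avian ND3 +1 frameshift (extra-cytosine) insertion.

Many bird mitogenomes carry a single extra cytosine about mid-way through
the ND3 coding sequence.  Translated naively it causes a premature stop, but
it is tolerated in vivo by programmed translational frameshifting.  Genomes
are classified WEC ("with extra cytosine") or WOC ("without") by combining
three signals against a WOC reference:

(i)   global pairwise alignment shows exactly one 1-nt cytosine insertion
      in the 5' two-thirds of the gene;
(ii)  naive translation of the query hits a premature stop downstream of
      the insertion;
(iii) deleting the inserted base restores an open reading frame through to
      the reference stop.

All three signals -> WEC; no insertion and a clean ORF -> WOC; anything
else -> ambiguous (never silently dropped).  Because the insertion sits in
a cytosine homopolymer its placement is inherently ambiguous; the reported
coordinate is the *leftmost* position of the run, which keeps calls
deterministic.  (Published coordinates for the same insertion differ
between sources for exactly this reason.)
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass

from Bio.Align import PairwiseAligner
from Bio.Data import CodonTable
from Bio.Seq import Seq

VERTEBRATE_MT_TABLE = 2


@dataclass
class FrameshiftCall:
    state: str                          # WEC / WOC / ambiguous
    insertion_position: int | None      # 1-based CDS coordinate, leftmost in run
    evidence: dict
    accession: str | None = None
    taxon: str | None = None
    order_name: str | None = None

    def __post_init__(self):
        if self.state not in {"WEC", "WOC", "ambiguous"}:
            raise ValueError(f"bad state {self.state!r}")
        # sequence-derived calls carry alignment evidence and obey the
        # position invariants; table-driven calls (no sequence seen) do not
        sequence_derived = "alignment_gap_pattern" in self.evidence
        if sequence_derived:
            if self.state == "WEC" and self.insertion_position is None:
                raise ValueError("WEC call requires an insertion position")
            if self.state == "WOC" and self.insertion_position is not None:
                raise ValueError("WOC call must not carry an insertion position")


@dataclass
class OrderSummary:
    order_name: str
    n_WEC: int
    n_WOC: int
    n_ambiguous: int


def _strip_trailing_partial_codon(seq: str) -> str:
    return seq[: len(seq) - (len(seq) % 3)] if len(seq) % 3 else seq


def _first_internal_stop(cds: str, table_id: int) -> int | None:
    """0-based codon index of the first stop before the final codon."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    seq = _strip_trailing_partial_codon(cds.upper())
    n_codons = len(seq) // 3
    for i in range(n_codons - 1):
        if seq[3 * i:3 * i + 3] in table.stop_codons:
            return i
    return None


def _longest_c_run(s: str) -> tuple[int, int]:
    """(length, 0-based start) of the leftmost longest cytosine run."""
    best_len, best_start = 0, -1
    i = 0
    while i < len(s):
        if s[i] == "C":
            j = i
            while j < len(s) and s[j] == "C":
                j += 1
            if j - i > best_len:
                best_len, best_start = j - i, i
            i = j
        else:
            i += 1
    return best_len, best_start


def _find_single_insertion(query: str, reference: str):
    """Align query to reference; return (position, char) of a single 1-nt
    insertion in the query, or None if the gap pattern is anything else.

    Position is the 1-based query coordinate, shifted to the leftmost
    position of the homopolymer run containing the inserted character.
    """
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -2
    aln = aligner.align(reference, query)[0]
    coords = aln.coordinates  # rows: (reference, query)
    insertions, deletions = [], []
    for k in range(coords.shape[1] - 1):
        dr = coords[0, k + 1] - coords[0, k]
        dq = coords[1, k + 1] - coords[1, k]
        if dr == 0 and dq > 0:
            # terminal raggedness (incomplete trailing codons) is not a
            # structural insertion
            if int(coords[0, k]) >= len(reference) - 3:
                continue
            insertions.append((int(coords[1, k]), int(dq)))
        elif dq == 0 and dr > 0:
            if int(coords[1, k]) >= len(query) - 3 or int(coords[0, k]) >= len(reference) - 3:
                continue
            deletions.append((int(coords[0, k]), int(dr)))
    if deletions or len(insertions) != 1 or insertions[0][1] != 1:
        return None
    qpos0, _ = insertions[0]
    # primary convention: the aligner's gap lands near the true site but
    # its exact placement is unreliable next to mismatches; if the longest
    # cytosine homopolymer near the gap is exactly one base longer in the
    # query than in the reference, the insertion sits in that run
    w = 15
    q_lo = max(0, qpos0 - w)
    q_len, q_off = _longest_c_run(query[q_lo:qpos0 + w + 1])
    r_lo = max(0, qpos0 - w - 1)
    r_len, _ = _longest_c_run(reference[r_lo:qpos0 + w])
    if q_len >= 2 and q_len == r_len + 1:
        return q_lo + q_off + 1, "C"
    # gap placement is ambiguous next to mismatches: refine by choosing the
    # single-base deletion (near the gap) that best restores the reference
    # ties broken toward the longest cytosine homopolymer (the insertion's
    # natural habitat), then leftmost: deterministic and immune to
    # compensating matches in divergent flanks
    def c_run_length(p: int) -> int:
        if query[p] != "C":
            return 0
        lo = hi = p
        while lo > 0 and query[lo - 1] == "C":
            lo -= 1
        while hi + 1 < len(query) and query[hi + 1] == "C":
            hi += 1
        return hi - lo + 1

    best = None
    for p in range(max(0, qpos0 - 8), min(len(query), qpos0 + 9)):
        cand = query[:p] + query[p + 1:]
        mism = sum(a != b for a, b in zip(cand, reference))
        key = (mism, -c_run_length(p), p)
        if best is None or key < best:
            best = key
    qpos0 = best[2]
    ch = query[qpos0]
    while qpos0 > 0 and query[qpos0 - 1] == ch:
        qpos0 -= 1
    return qpos0 + 1, ch


def classify_nd3(cds: str, reference_woc: str,
                 code: int = VERTEBRATE_MT_TABLE, **meta) -> FrameshiftCall:
    """Classify one ND3 coding sequence as WEC / WOC / ambiguous.

    ``reference_woc`` is a frameshift-free ND3 CDS (a passerine sequence is
    conventional for real surveys).  Extra keyword arguments (accession,
    taxon, order_name) are attached to the call.
    """
    query = cds.upper().replace("U", "T")
    ref = reference_woc.upper().replace("U", "T")
    if len(query) < len(ref) / 2:
        raise ValueError(
            f"query ({len(query)} nt) shorter than half the reference ({len(ref)} nt)"
        )
    hit = _find_single_insertion(query, ref)
    in_five_prime = hit is not None and hit[0] <= (2 * len(ref)) / 3
    is_cytosine = hit is not None and hit[1] == "C"
    gap_signal = hit is not None and is_cytosine and in_five_prime

    stop_idx = _first_internal_stop(query, code)
    stop_signal = (gap_signal and stop_idx is not None
                   and 3 * stop_idx + 3 > hit[0])

    orf_signal = False
    if hit is not None:
        pos0 = hit[0] - 1
        deleted = query[:pos0] + query[pos0 + 1:]
        orf_signal = _first_internal_stop(deleted, code) is None

    evidence = {
        "length_mod3": len(query) % 3,
        "alignment_gap_pattern": bool(gap_signal),
        "downstream_stop_with_insertion": bool(stop_signal),
        "orf_restored_on_deletion": bool(orf_signal),
    }
    if gap_signal and stop_signal and orf_signal:
        return FrameshiftCall(state="WEC", insertion_position=hit[0],
                              evidence=evidence, **meta)
    clean_orf = _first_internal_stop(query, code) is None
    if hit is None and clean_orf:
        return FrameshiftCall(state="WOC", insertion_position=None,
                              evidence=evidence, **meta)
    return FrameshiftCall(state="ambiguous",
                          insertion_position=hit[0] if hit else None,
                          evidence=evidence, **meta)


def survey(calls: list[FrameshiftCall],
           order_display: list[str] | None = None) -> list[OrderSummary]:
    """Tally WEC/WOC/ambiguous calls per taxonomic order.

    Calls without an order are tallied under 'unassigned' with a warning.
    Rows follow ``order_display`` when given (a phylogenetic display
    order), otherwise alphabetical order.
    """
    tallies: dict[str, dict] = defaultdict(lambda: {"WEC": 0, "WOC": 0, "ambiguous": 0})
    for c in calls:
        order = c.order_name
        if not order:
            warnings.warn(f"call for {c.accession or c.taxon!r} lacks order_name; "
                          "counted under 'unassigned'")
            order = "unassigned"
        tallies[order][c.state] += 1
    if order_display:
        names = [o for o in order_display if o in tallies]
        names += sorted(set(tallies) - set(names))
    else:
        names = sorted(tallies)
    return [OrderSummary(order_name=o, n_WEC=tallies[o]["WEC"],
                         n_WOC=tallies[o]["WOC"],
                         n_ambiguous=tallies[o]["ambiguous"]) for o in names]


def read_state_table(path) -> list[FrameshiftCall]:
    """Per-species ND3 state table: accession <tab> taxon <tab> order <tab> state.

    'state' is WEC or WOC (a pre-classified survey table); calls built this
    way carry no sequence evidence."""
    calls = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("accession\t"):
                continue
            acc, taxon, order, state = line.split("\t")
            calls.append(FrameshiftCall(
                state=state, insertion_position=None,
                evidence={"source": "state table"},
                accession=acc, taxon=taxon, order_name=order,
            ))
    return calls


def survey_to_tsv(summaries: list[OrderSummary], path) -> None:
    with open(path, "w") as fh:
        fh.write("order\tn_WEC\tn_WOC\tn_ambiguous\n")
        for s in summaries:
            fh.write(f"{s.order_name}\t{s.n_WEC}\t{s.n_WOC}\t{s.n_ambiguous}\n")


def calls_to_tsv(calls: list[FrameshiftCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\ttaxon\torder\tstate\tinsertion_position\n")
        for c in calls:
            fh.write(f"{c.accession or ''}\t{c.taxon or ''}\t{c.order_name or ''}\t"
                     f"{c.state}\t{c.insertion_position if c.insertion_position else ''}\n")
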