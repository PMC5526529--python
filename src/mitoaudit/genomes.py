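"""Mitogenome records: GenBank/FASTA I/O, gene extraction, descriptive statistics.

Coordinates are 1-based inclusive throughout (GenBank convention).  Features
that span the circular origin are represented with ``wraps_origin=True``
rather than negative arithmetic.  Conversion to Python's half-open 0-based
slices happens only inside this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

#: The 13 mitochondrial protein-coding genes in avian genome order.
PCG_ORDER = [
    "ND1", "ND2", "COX1", "COX2", "ATP8", "ATP6", "COX3",
    "ND3", "ND4L", "ND4", "ND5", "CYTB", "ND6",
]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

_UNAMBIGUOUS = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    """Reverse complement with IUPAC ambiguity support."""
    return seq.translate(_COMPLEMENT)[::-1]


def _load_synonym_map() -> dict:
    mapping = {}
    text = resources.files("mitoaudit.data").joinpath("gene_synonyms.tsv").read_text()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        canonical, synonym = line.split("\t")
        mapping[synonym.strip().upper()] = canonical
    return mapping


GENE_SYNONYMS = _load_synonym_map()


def canonical_gene_name(name: str) -> str | None:
    """Map a gene label to its canonical symbol, or None when unmappable."""
    return GENE_SYNONYMS.get(name.strip().upper())


@dataclass
class Feature:
    """One annotated feature on a mitogenome.

    ``start``/``end`` are 1-based inclusive genome coordinates.  For a
    feature wrapping the circular origin, ``start > end`` and
    ``wraps_origin`` is True.
    """

    kind: str  # CDS, tRNA, rRNA, D-loop, other
    gene_name: str | None
    start: int
    end: int
    strand: str = "+"
    wraps_origin: bool = False

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1:
            raise ValueError("coordinates are 1-based; start < 1")
        if not self.wraps_origin and self.end < self.start:
            raise ValueError(
                f"end < start ({self.end} < {self.start}) without wraps_origin"
            )

    def length(self, genome_length: int | None = None) -> int:
        if self.wraps_origin:
            if genome_length is None:
                raise ValueError("genome_length required for origin-spanning feature")
            return (genome_length - self.start + 1) + self.end
        return self.end - self.start + 1


@dataclass
class BaseComposition:
    pct_A: float
    pct_C: float
    pct_G: float
    pct_T: float
    n_ambiguous: int = 0

    def as_dict(self) -> dict:
        return {
            "pct_A": self.pct_A, "pct_C": self.pct_C,
            "pct_G": self.pct_G, "pct_T": self.pct_T,
            "n_ambiguous": self.n_ambiguous,
        }


@dataclass
class AnnotatedGenome:
    """A mitochondrial genome with typed features."""

    accession: str
    taxon: str
    sequence: str
    features: list[Feature] = field(default_factory=list)
    order_name: str | None = None
    circular: bool = True

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise ValueError(f"{self.accession}: empty sequence")
        self.sequence = self.sequence.upper()
        for f in self.features:
            hi = self.end_coordinate(f)
            if f.start > len(self.sequence) or (not f.wraps_origin and f.end > len(self.sequence)):
                raise ValueError(
                    f"{self.accession}: feature {f.gene_name or f.kind} interval "
                    f"[{f.start},{f.end}] outside [1,{len(self.sequence)}]"
                )
            del hi

    def end_coordinate(self, f: Feature) -> int:
        return f.end if not f.wraps_origin else len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def features_of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    def find_gene(self, gene_name: str) -> list[Feature]:
        target = canonical_gene_name(gene_name) or gene_name.upper()
        return [f for f in self.features
                if f.gene_name is not None and f.gene_name.upper() == target]


class GenBankParseError(ValueError):
    pass


def _classify_feature(biofeat: SeqFeature) -> tuple[str, str | None]:
    ftype = biofeat.type
    quals = biofeat.qualifiers
    label = None
    for key in ("gene", "product", "note"):
        if key in quals and quals[key]:
            label = quals[key][0]
            break
    if ftype == "CDS":
        name = canonical_gene_name(label) if label else None
        if name is None:
            warnings.warn(f"CDS with unmappable gene name {label!r}; kept as kind='other'")
            return "other", label
        return "CDS", name
    if ftype == "tRNA":
        return "tRNA", label
    if ftype == "rRNA":
        return "rRNA", label
    if ftype in {"D-loop", "misc_feature"} and (
        ftype == "D-loop" or (label and "control region" in label.lower())
    ):
        return "D-loop", label
    return "other", label


def _location_to_interval(loc) -> tuple[int, int, bool]:
    """Biopython location -> (start, end, wraps_origin), 1-based inclusive."""
    if isinstance(loc, CompoundLocation) and len(loc.parts) == 2:
        a, b = loc.parts
        # join(x..L,1..y) across the circular origin
        if int(b.start) == 0:
            return int(a.start) + 1, int(b.end), True
    return int(loc.start) + 1, int(loc.end), False


def read_genbank(path: str | Path) -> list[AnnotatedGenome]:
    """Read a (possibly multi-record) GenBank flat file.

    CDS features carry canonical gene names; a CDS whose label cannot be
    mapped is kept with ``kind='other'`` and a warning, never dropped.
    """
    genomes = []
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise GenBankParseError(f"cannot parse {path}: {exc}") from exc
    if not records:
        raise GenBankParseError(f"{path}: no GenBank records found")
    for rec in records:
        feats = []
        for bf in rec.features:
            if bf.type == "source":
                continue
            kind, name = _classify_feature(bf)
            if kind == "other" and bf.type not in {"CDS", "tRNA", "rRNA", "D-loop", "misc_feature"}:
                continue
            start, end, wraps = _location_to_interval(bf.location)
            strand = "-" if bf.location.strand == -1 else "+"
            feats.append(Feature(kind=kind, gene_name=name, start=start, end=end,
                                 strand=strand, wraps_origin=wraps))
        taxon = rec.annotations.get("organism", rec.description or rec.id)
        topology = rec.annotations.get("topology", "circular")
        taxonomy = rec.annotations.get("taxonomy") or []
        order_name = next((t for t in taxonomy if t.endswith("formes")), None)
        genomes.append(AnnotatedGenome(
            accession=rec.id, taxon=taxon, sequence=str(rec.seq),
            features=feats, order_name=order_name,
            circular=(topology == "circular"),
        ))
    return genomes


def write_genbank(genomes: Iterable[AnnotatedGenome], path: str | Path) -> None:
    """Write genomes as a GenBank flat file (synthetic-data round-trip writer)."""
    records = []
    for g in genomes:
        rec = SeqRecord(Seq(g.sequence), id=g.accession, name=g.accession.split(".")[0],
                        description=f"{g.taxon} mitochondrion, complete genome")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = "circular" if g.circular else "linear"
        rec.annotations["organism"] = g.taxon
        if g.order_name:
            rec.annotations["taxonomy"] = ["Aves", g.order_name]
        for f in g.features:
            strand = -1 if f.strand == "-" else 1
            if f.wraps_origin:
                loc = CompoundLocation([
                    SimpleLocation(f.start - 1, len(g.sequence), strand),
                    SimpleLocation(0, f.end, strand),
                ])
            else:
                loc = SimpleLocation(f.start - 1, f.end, strand)
            ftype = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                     "D-loop": "D-loop"}.get(f.kind, "misc_feature")
            quals = {}
            if f.gene_name:
                quals["gene"] = [f.gene_name]
            rec.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def extract_gene(genome: AnnotatedGenome, gene_name: str) -> str:
    """Return the coding-strand sequence of a gene.

    Minus-strand genes (ND6 in birds) are reverse-complemented;
    origin-spanning genes are unwrapped.
    """
    hits = genome.find_gene(gene_name)
    if len(hits) != 1:
        present = sorted({f.gene_name for f in genome.features if f.gene_name})
        raise ValueError(
            f"{genome.accession}: gene {gene_name!r} present {len(hits)} times; "
            f"annotated genes: {present}"
        )
    f = hits[0]
    if f.wraps_origin:
        raw = genome.sequence[f.start - 1:] + genome.sequence[:f.end]
    else:
        raw = genome.sequence[f.start - 1:f.end]
    return reverse_complement(raw) if f.strand == "-" else raw


def base_composition(sequence: str) -> BaseComposition:
    """Percent A/C/G/T over unambiguous bases; ambiguity counted separately."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    n_amb = len(seq) - total
    if total == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return BaseComposition(
        pct_A=100.0 * counts["A"] / total,
        pct_C=100.0 * counts["C"] / total,
        pct_G=100.0 * counts["G"] / total,
        pct_T=100.0 * counts["T"] / total,
        n_ambiguous=n_amb,
    )


def gene_table(genomes: Iterable[AnnotatedGenome]) -> "pandas.DataFrame":  # noqa: F821
    """Feature table (accession, gene, kind, start, end, strand, length) for TSV export."""
    import pandas as pd

    rows = []
    for g in genomes:
        for f in g.features:
            rows.append({
                "accession": g.accession, "taxon": g.taxon,
                "gene": f.gene_name or "", "kind": f.kind,
                "start": f.start, "end": f.end, "strand": f.strand,
                "wraps_origin": f.wraps_origin,
                "length": f.length(len(g.sequence)),
            })
    return pd.DataFrame(rows)
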