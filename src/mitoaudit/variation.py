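"""Variable-site (SNP) profiling and the hotspot colocation permutation test.

Variable sites among aligned mitogenomes are counted in fixed-width bins
(default 60 nt).  Bins containing candidate positively-selected sites are
compared with the remaining bins by a Fisher-Pitman style permutation test
on the raw difference of mean per-bin SNP rates: the bin, not the site, is
the exchangeable unit, and the flag vector is permuted over bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VariableSites:
    """1-based variable positions plus the gap columns excluded from the scan."""
    positions: list[int]
    gap_columns: list[int]
    length: int


def variable_sites(rows: list[str]) -> VariableSites:
    """Positions (1-based) where >= 2 distinct unambiguous bases occur.

    Columns containing an alignment gap in any sequence are excluded from
    consideration entirely and reported separately.
    """
    if len(rows) < 2:
        raise ValueError("need >= 2 sequences")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"sequences differ in length: {sorted(lengths)}")
    arr = np.array([list(r.upper()) for r in rows], dtype="U1")
    has_gap = (arr == "-").any(axis=0)
    unamb = np.isin(arr, list("ACGT"))
    n_distinct = np.zeros(arr.shape[1], dtype=int)
    for b in "ACGT":
        n_distinct += ((arr == b) & unamb).any(axis=0)
    variable = (n_distinct >= 2) & ~has_gap
    return VariableSites(
        positions=[int(i) + 1 for i in np.flatnonzero(variable)],
        gap_columns=[int(i) + 1 for i in np.flatnonzero(has_gap)],
        length=arr.shape[1],
    )


@dataclass
class BinProfile:
    bin_width: int
    length: int
    starts: np.ndarray            # 1-based inclusive bin starts
    ends: np.ndarray              # 1-based inclusive bin ends
    counts: np.ndarray
    rates: np.ndarray
    candidate_flags: np.ndarray
    candidate_sites: dict[int, str] = field(default_factory=dict)  # pos -> tier
    n_excluded_columns: int = 0

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("bin_start\tbin_end\tcount\trate\tcandidate\n")
            for s, e, c, r, f in zip(self.starts, self.ends, self.counts,
                                     self.rates, self.candidate_flags):
                fh.write(f"{s}\t{e}\t{c}\t{r:.6f}\t{int(f)}\n")


def bin_profile(positions, length: int, bin_width: int = 60,
                candidates=None, excluded_columns=None) -> BinProfile:
    """Bin variable-site positions into non-overlapping windows anchored at 1.

    Bin k covers [(k-1)w+1, min(kw, L)]; the last bin may be short and its
    rate uses its true width.  Columns listed in ``excluded_columns`` (gap
    columns) are removed from bin denominators.  ``candidates`` maps 1-based
    positions to a tier label ('potential' or 'significant'), or is a plain
    iterable of positions (tier defaults to 'potential'); a bin is flagged
    when at least one candidate site falls inside it.
    """
    if bin_width < 1 or length < 1:
        raise ValueError("length and bin_width must be positive")
    positions = np.asarray(sorted(positions), dtype=int)
    if len(positions) and (positions[0] < 1 or positions[-1] > length):
        raise ValueError("variable positions outside [1, L]")
    if candidates is None:
        candidates = {}
    elif not isinstance(candidates, dict):
        candidates = {int(p): "potential" for p in candidates}
    for p in candidates:
        if not (1 <= p <= length):
            raise ValueError(f"candidate site {p} outside [1, {length}]")
    excluded = np.asarray(sorted(set(excluded_columns or [])), dtype=int)

    n_bins = (length + bin_width - 1) // bin_width
    starts = np.arange(n_bins) * bin_width + 1
    ends = np.minimum(starts + bin_width - 1, length)
    widths = (ends - starts + 1).astype(float)
    counts = np.bincount((positions - 1) // bin_width, minlength=n_bins)
    if len(excluded):
        widths -= np.bincount((excluded - 1) // bin_width, minlength=n_bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(widths > 0, counts / np.maximum(widths, 1e-300), 0.0)
    flags = np.zeros(n_bins, dtype=bool)
    for p in candidates:
        flags[(p - 1) // bin_width] = True
    return BinProfile(
        bin_width=bin_width, length=length, starts=starts, ends=ends,
        counts=counts, rates=rates, candidate_flags=flags,
        candidate_sites=dict(candidates), n_excluded_columns=len(excluded),
    )


@dataclass
class PermutationResult:
    observed_statistic: float
    p_value: float
    n_permutations: int
    seed: int
    alternative: str
    null_mean: float
    null_sd: float
    unit: str = "bin"  # exchangeable unit of the test

    def as_dict(self) -> dict:
        return {
            "observed_statistic": self.observed_statistic,
            "p_value": self.p_value, "n_permutations": self.n_permutations,
            "seed": self.seed, "alternative": self.alternative,
            "null_mean": self.null_mean, "null_sd": self.null_sd,
            "unit": self.unit,
        }


def hotspot_association_test(profile: BinProfile, n_permutations: int = 9999,
                             seed: int = 0,
                             alternative: str = "greater") -> PermutationResult:
    """Fisher-Pitman style permutation test for elevated SNP rates in
    candidate-flagged bins.

    The statistic is (mean rate of flagged bins) - (mean rate of the rest);
    the null is built by permuting the flag vector over bins, with the
    add-one p-value (1 + #{null >= observed}) / (1 + n_permutations).
    """
    if alternative not in {"greater", "two-sided"}:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    flags = np.asarray(profile.candidate_flags, dtype=bool)
    rates = np.asarray(profile.rates, dtype=float)
    k, m = int(flags.sum()), len(flags)
    if k == 0:
        raise ValueError("no candidate sites supplied")
    if k == m:
        raise ValueError("every bin is candidate-flagged; no comparison group")
    total = rates.sum()

    def stat_from_flag_sum(s):
        return s / k - (total - s) / (m - k)

    observed = stat_from_flag_sum(rates[flags].sum())
    rng = np.random.default_rng(seed)
    # permute flags: choose k bins uniformly without replacement per
    # replicate; drawing from the sorted rates makes the sampled null (and
    # hence the p-value) exactly invariant to bin ordering
    sorted_rates = np.sort(rates)
    order = np.argsort(rng.random((n_permutations, m)), axis=1)[:, :k]
    null = stat_from_flag_sum(sorted_rates[order].sum(axis=1))
    if alternative == "greater":
        exceed = int((null >= observed - 1e-15).sum())
    else:
        exceed = int((np.abs(null) >= abs(observed) - 1e-15).sum())
    p = (1 + exceed) / (1 + n_permutations)
    return PermutationResult(
        observed_statistic=float(observed), p_value=float(p),
        n_permutations=n_permutations, seed=seed, alternative=alternative,
        null_mean=float(null.mean()), null_sd=float(null.std(ddof=1)),
    )


# ------------------------------------------------ candidate-site plumbing

def codon_to_positions(codon_index: int, gene_start: int) -> list[int]:
    """Map a 1-based protein (codon) site to its three nucleotide positions,
    given the 1-based position of the gene's first coding nucleotide."""
    first = gene_start + 3 * (codon_index - 1)
    return [first, first + 1, first + 2]


def candidates_from_codon_table(table, gene_starts: dict[str, int]) -> dict[int, str]:
    """Expand (gene, codon_index, tier) records into {position: tier}.

    ``gene_starts`` maps gene name to the 1-based coordinate of the gene's
    first nucleotide in the target coordinate system (genome or supermatrix).
    All three codon positions receive the codon's tier; 'significant'
    outranks 'potential' when codons overlap.
    """
    out: dict[int, str] = {}
    for gene, codon, tier in table:
        if gene not in gene_starts:
            raise ValueError(f"unknown gene {gene!r} in candidate table")
        for p in codon_to_positions(int(codon), gene_starts[gene]):
            if out.get(p) != "significant":
                out[p] = tier
    return out


def read_candidates_tsv(path) -> list[tuple[str, int, str]]:
    """Candidate-site list as TSV: gene <tab> codon_index <tab> tier."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("gene\t"):
                continue
            gene, codon, tier = line.split("\t")
            if tier not in {"potential", "significant"}:
                raise ValueError(f"bad tier {tier!r}")
            rows.append((gene, int(codon), tier))
    return rows


def read_candidates_bed(path) -> list[int]:
    """BED (0-based half-open) candidate intervals -> 1-based positions."""
    positions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            start, end = int(parts[1]), int(parts[2])
            positions.extend(range(start + 1, end + 1))
    return positions
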