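"""Substitution-saturation assessment.

Two diagnostics are provided:

* transition/transversion trajectories against pairwise divergence
  (the classic saturation plot: transversions overtaking transitions at
  deep divergences signals multiple hits), and
* an entropy-based saturation index in the style of Xia's Iss: the mean
  per-site entropy of the alignment (bits) divided by the expected
  per-site entropy at full saturation, with a Monte-Carlo critical value
  Iss.c defined as the index level at which a distance method's
  topology-recovery probability collapses.

Under Xia's construction, *little* saturation corresponds to Iss
significantly **below** Iss.c.  Reports always print both values and the
decision rule, since the inequality direction is a common source of
confusion in the literature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .supermatrix import Supermatrix
from .infer import encode, neighbor_joining, DistanceMatrix

SUBSAMPLE_SIZES = (4, 8, 16, 32)


@dataclass
class PairProfile:
    taxon_a: str
    taxon_b: str
    n_sites: int
    p_distance: float
    proportion_transitions: float
    proportion_transversions: float


def _selector_columns(sm: Supermatrix, subset: str) -> np.ndarray:
    if subset == "all":
        return np.arange(sm.width)
    if subset in {"pos1", "pos2", "pos3"}:
        want = int(subset[-1])
        return np.flatnonzero(sm.codon_positions == want)
    raise ValueError(f"selector must be pos1/pos2/pos3/all, got {subset!r}")


def pairwise_profiles(sm: Supermatrix, subset: str = "all") -> list[PairProfile]:
    """Per-pair p-distance split into transition and transversion proportions.

    Sites with a gap or ambiguity in either sequence are excluded.
    Transitions are A<->G and C<->T.
    """
    cols = _selector_columns(sm, subset)
    if len(cols) == 0:
        raise ValueError(f"selector {subset!r} selects no columns")
    codes = [encode(r)[cols] for r in sm.rows]
    out = []
    for i in range(sm.n_taxa):
        for j in range(i + 1, sm.n_taxa):
            a, b = codes[i], codes[j]
            ok = (a >= 0) & (b >= 0)
            n = int(ok.sum())
            if n == 0:
                raise ValueError(
                    f"no comparable sites for pair {sm.taxa[i]}/{sm.taxa[j]}"
                )
            aa, bb = a[ok], b[ok]
            diff = aa != bb
            same_type = ((aa % 2) == (bb % 2))  # both purine or both pyrimidine
            ts = int((diff & same_type).sum())
            tv = int((diff & ~same_type).sum())
            out.append(PairProfile(
                taxon_a=sm.taxa[i], taxon_b=sm.taxa[j], n_sites=n,
                p_distance=(ts + tv) / n,
                proportion_transitions=ts / n,
                proportion_transversions=tv / n,
            ))
    return out


def profiles_to_tsv(profiles: list[PairProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon_a\ttaxon_b\tn_sites\tp_distance\ttransitions\ttransversions\n")
        for p in profiles:
            fh.write(f"{p.taxon_a}\t{p.taxon_b}\t{p.n_sites}\t{p.p_distance:.6f}\t"
                     f"{p.proportion_transitions:.6f}\t{p.proportion_transversions:.6f}\n")


# ------------------------------------------------------------------ Iss

def _site_entropies(rows: list[str]) -> np.ndarray:
    """Per-column entropy (bits) over observed unambiguous bases."""
    codes = np.stack([encode(r) for r in rows])
    L = codes.shape[1]
    counts = np.zeros((4, L))
    for b in range(4):
        counts[b] = (codes == b).sum(axis=0)
    tot = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(tot > 0, counts / np.maximum(tot, 1), 0.0)
        h = np.where(p > 0, -p * np.log2(p), 0.0).sum(axis=0)
    return h


def full_saturation_entropy(n_otus: int, base_freqs) -> float:
    """Expected per-site entropy (bits) at full saturation: each of the n
    sequences' bases is an independent draw from the stationary frequencies.
    Computed exactly by enumerating base-count compositions of n."""
    f = np.asarray(base_freqs, dtype=float)
    f = f / f.sum()
    logf = np.log(np.maximum(f, 1e-300))
    expected = 0.0
    n = n_otus
    for na in range(n + 1):
        for nc in range(n + 1 - na):
            for ng in range(n + 1 - na - nc):
                nt = n - na - nc - ng
                ks = np.array([na, nc, ng, nt])
                logp = (gammaln(n + 1) - gammaln(ks + 1).sum()
                        + (ks * logf).sum())
                props = ks / n
                h = float(np.where(props > 0, -props * np.log2(np.maximum(props, 1e-300)), 0).sum())
                expected += math.exp(logp) * h
    return expected


def iss(sm_or_rows, base_freqs=None) -> float:
    """Entropy-based saturation index: mean per-site entropy divided by the
    full-saturation entropy for this number of sequences and these
    alignment-wide base frequencies.  0 for an all-invariant alignment,
    approaching 1 for an alignment of independent random bases."""
    rows = sm_or_rows.rows if isinstance(sm_or_rows, Supermatrix) else list(sm_or_rows)
    if len(rows) < 4:
        raise ValueError("need >= 4 sequences")
    h = _site_entropies(rows)
    if base_freqs is None:
        codes = np.stack([encode(r) for r in rows])
        counts = np.array([(codes == b).sum() for b in range(4)], dtype=float)
        if counts.sum() == 0:
            raise ValueError("no unambiguous bases in alignment")
        base_freqs = counts / counts.sum()
    h_fs = full_saturation_entropy(len(rows), base_freqs)
    if h_fs == 0:
        return 0.0
    value = float(h.mean() / h_fs)
    if value == 0.0:
        warnings.warn("alignment is entirely invariant; Iss = 0")
    return value


def iss_subsampled(sm: Supermatrix, n_otus: int, draws: int = 10,
                   seed: int = 0) -> float:
    """Average Iss over random subsets of ``n_otus`` taxa (the conventional
    4/8/16/32-OTU protocol for large alignments)."""
    if n_otus > sm.n_taxa:
        raise ValueError("n_otus exceeds available taxa")
    if n_otus == sm.n_taxa:
        return iss(sm)
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(draws):
        pick = rng.choice(sm.n_taxa, size=n_otus, replace=False)
        vals.append(iss([sm.rows[i] for i in pick]))
    return float(np.mean(vals))


# ------------------------------------------------- critical value machinery

@dataclass
class IssCritical:
    iss_c: float
    n_otus: int
    seq_length: int
    replicate_iss: np.ndarray       # Iss replicates at the critical ladder step
    recovery_by_step: list[float]
    iss_by_step: list[float]
    scales: list[float]
    seed: int


@dataclass
class IssResult:
    iss: float
    iss_c: float
    p_value: float
    n_otus_subsampled: int
    replicate_count: int
    decision: str                    # little-saturation / substantial-saturation
    rule: str = ("little-saturation iff Iss is significantly below Iss.c "
                 "(t-test, alpha 0.05); both values always reported")


def _random_topology(n: int, rng) -> list[tuple[int, int, int]]:
    """Random unrooted binary tree by stepwise addition.  Returns an edge
    list as (parent, child, is_leaf_child) over node ids; leaves are 0..n-1."""
    # Build as rooted-at-node structure: maintain edges; insert each new leaf
    # on a uniformly chosen edge.
    edges = [(n, 0), (n, 1), (n, 2)]  # central node n joins leaves 0,1,2
    next_internal = n + 1
    for leaf in range(3, n):
        k = rng.integers(0, len(edges))
        a, b = edges.pop(k)
        mid = next_internal
        next_internal += 1
        edges += [(a, mid), (mid, b), (mid, leaf)]
    return edges


def _simulate_jc_on_edges(edges, n_leaves: int, scale: float, L: int, rng):
    """JC69 simulation over a random topology; per-edge length ~ U(0.5,1.5)*scale."""
    children: dict[int, list[int]] = {}
    nodes = set()
    for a, b in edges:
        children.setdefault(a, []).append(b)
        nodes.update((a, b))
    root = next(iter(children))
    # find true root (node never appearing as child)
    child_set = {b for _, b in edges}
    root = next(x for x in nodes if x not in child_set)
    states = {root: rng.integers(0, 4, size=L)}
    stack = [root]
    while stack:
        u = stack.pop()
        for v in children.get(u, []):
            t = float(rng.uniform(0.5, 1.5)) * scale
            p_change = 0.75 * (1 - math.exp(-4 * t / 3))
            s = states[u].copy()
            hit = rng.random(L) < p_change
            # draw a different base uniformly for hit sites
            s[hit] = (s[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
            states[v] = s
            stack.append(v)
    leaf_states = np.stack([states[i] for i in range(n_leaves)])
    bases = np.array(list("ACGT"))
    rows = ["".join(bases[s]) for s in leaf_states]
    true_splits = _edge_splits(edges, n_leaves)
    return rows, true_splits


def _edge_splits(edges, n_leaves: int) -> set[frozenset]:
    children: dict[int, list[int]] = {}
    for a, b in edges:
        children.setdefault(a, []).append(b)

    def leafset(x):
        if x < n_leaves:
            return frozenset([x])
        out = frozenset()
        for c in children.get(x, []):
            out |= leafset(c)
        return out

    splits = set()
    full = frozenset(range(n_leaves))
    for a, b in edges:
        side = leafset(b)
        if 0 in side:
            side = full - side
        if 2 <= len(side) <= n_leaves - 2:
            splits.add(side)
    return splits


def _nj_splits(rows: list[str]) -> set[frozenset]:
    from .trees import bipartitions

    taxa = [f"L{i:03d}" for i in range(len(rows))]
    dm = distance_p_matrix(rows, taxa)
    tree = neighbor_joining(dm)
    full = frozenset(taxa)
    return {frozenset(int(x[1:]) for x in side) for side in bipartitions(tree)}


def distance_p_matrix(rows: list[str], taxa: list[str]) -> DistanceMatrix:
    codes = np.stack([encode(r) for r in rows])
    n = len(rows)
    m = np.zeros((n, n))
    for i in range(n):
        diff = codes[i][None, :] != codes
        m[i] = diff.mean(axis=1)
    np.fill_diagonal(m, 0.0)
    m = 0.5 * (m + m.T)
    return DistanceMatrix(taxa=taxa, matrix=m)


def iss_critical(n_otus: int = 8, seq_length: int = 1000, replicates: int = 500,
                 seed: int = 0, recovery_threshold: float = 0.95,
                 scales=None) -> IssCritical:
    """Monte-Carlo critical value Iss.c.

    Alignments are simulated on random topologies along a ladder of
    increasing tree depths; at each depth, the proportion of replicates in
    which neighbor joining on p-distances recovers the true topology is
    measured.  Iss.c is the mean Iss at the first depth where recovery
    drops below ``recovery_threshold``.
    """
    if n_otus < 4:
        raise ValueError("n_otus >= 4 required")
    if replicates < 100:
        warnings.warn("fewer than 100 replicates: critical value may be unstable")
    if scales is None:
        # deep tail included so recovery genuinely collapses on long alignments
        scales = [0.01, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6, 3.2, 6.4, 12.8, 25.6]
    rng = np.random.default_rng(seed)
    recovery, mean_iss, iss_reps = [], [], []
    for scale in scales:
        hits = 0
        vals = np.empty(replicates)
        for r in range(replicates):
            edges = _random_topology(n_otus, rng)
            rows, true_splits = _simulate_jc_on_edges(edges, n_otus, scale,
                                                      seq_length, rng)
            vals[r] = iss(rows, base_freqs=[0.25] * 4)
            if _nj_splits(rows) == true_splits:
                hits += 1
        recovery.append(hits / replicates)
        mean_iss.append(float(vals.mean()))
        iss_reps.append(vals)
    crit_idx = next((k for k, rec in enumerate(recovery)
                     if rec < recovery_threshold), len(scales) - 1)
    return IssCritical(
        iss_c=mean_iss[crit_idx], n_otus=n_otus, seq_length=seq_length,
        replicate_iss=iss_reps[crit_idx], recovery_by_step=recovery,
        iss_by_step=mean_iss, scales=list(scales), seed=seed,
    )


def saturation_test(sm: Supermatrix, replicates: int = 500, seed: int = 0,
                    subsample_draws: int = 10) -> IssResult:
    """Full saturation assessment of an alignment.

    The observed index is compared against the Monte-Carlo Iss.c for the
    matched number of OTUs (subsampled to the nearest of 4/8/16/32) via a
    one-sample t-test on the replicate distribution at the critical depth.
    """
    n_sub = max(s for s in SUBSAMPLE_SIZES if s <= max(sm.n_taxa, 4))
    n_sub = min(n_sub, sm.n_taxa)
    if n_sub < 4:
        raise ValueError("need >= 4 taxa")
    observed = iss_subsampled(sm, n_sub, draws=subsample_draws, seed=seed)
    crit = iss_critical(n_otus=n_sub, seq_length=sm.width,
                        replicates=replicates, seed=seed)
    reps = crit.replicate_iss
    sd = float(reps.std(ddof=1)) if len(reps) > 1 else 0.0
    if sd == 0:
        p = 1.0 if observed >= crit.iss_c else 1e-12
    else:
        t = (observed - crit.iss_c) / sd
        p = float(stats.t.sf(abs(t), df=len(reps) - 1) * 2)
    p = min(max(p, 1e-12), 1.0)
    # saturation is only ruled out when Iss sits significantly below Iss.c
    little = observed < crit.iss_c and p < 0.05
    return IssResult(iss=observed, iss_c=crit.iss_c, p_value=p,
                     n_otus_subsampled=n_sub, replicate_count=replicates,
                     decision="little-saturation" if little else "substantial-saturation")
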