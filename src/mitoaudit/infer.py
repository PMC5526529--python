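"""Desk-scale tree inference: closed-form distances, neighbor joining,
bootstrap support, and the per-gene / leave-one-gene-out influence audit.

This module deliberately uses NJ over closed-form distance estimators
(p, JC69, K80, TN93) rather than full likelihood or Bayesian machinery:
the audit framework — which gene drives the consensus topology, and what
happens when it is excluded — is exact and fast at this scale, and is
validated on simulated data where the per-partition truth is known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import dendropy

from .supermatrix import Supermatrix
from .trees import classify_arborophila, parse_newick, rf_distance

MODELS = ("p", "JC69", "K80", "TN93")

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as int8 codes A=0 C=1 G=2 T=3, anything else -1."""
    arr = np.full(len(seq), -1, dtype=np.int8)
    for base, code in _CODE.items():
        arr[np.frombuffer(seq.encode(), dtype="S1") == base.encode()] = code
    return arr


def _pair_counts(a: np.ndarray, b: np.ndarray):
    ok = (a >= 0) & (b >= 0)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no comparable (unambiguous, ungapped) sites")
    aa, bb = a[ok], b[ok]
    diff = aa != bb
    purine_a = (aa == 0) | (aa == 2)
    purine_b = (bb == 0) | (bb == 2)
    ts = diff & (purine_a == purine_b)          # A<->G or C<->T
    p1 = diff & purine_a & purine_b             # A<->G
    p2 = diff & ~purine_a & ~purine_b           # C<->T
    tv = diff & (purine_a != purine_b)
    freqs = np.bincount(np.concatenate([aa, bb]), minlength=4) / (2 * n)
    return n, diff.sum() / n, ts.sum() / n, tv.sum() / n, p1.sum() / n, p2.sum() / n, freqs


def _safe_log(x: float) -> float:
    return math.log(x) if x > 0 else -math.inf


def distance(seq1: str, seq2: str, model: str = "K80") -> float:
    """Pairwise distance under a closed-form estimator.

    Sites with a gap or ambiguity in either sequence are excluded.  When a
    logarithm argument is non-positive (saturation), ``math.inf`` is
    returned rather than raising.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    if len(seq1) != len(seq2):
        raise ValueError("sequences differ in length")
    a, b = encode(seq1.upper()), encode(seq2.upper())
    n, p, ts, tv, p1, p2, f = _pair_counts(a, b)
    if model == "p":
        return p
    if model == "JC69":
        return max(0.0, -0.75 * _safe_log(1 - 4 * p / 3))
    if model == "K80":
        d = -0.5 * _safe_log(1 - 2 * ts - tv) - 0.25 * _safe_log(1 - 2 * tv)
        return max(0.0, d)
    # TN93
    pa, pc, pg, pt = f
    gr, gy = pa + pg, pc + pt
    if min(pa, pc, pg, pt) <= 0:
        # degenerate frequencies: fall back to K80 form
        return distance(seq1, seq2, "K80")
    k1 = 2 * pa * pg / gr
    k2 = 2 * pc * pt / gy
    k3 = 2 * (gr * gy - pa * pg * gy / gr - pc * pt * gr / gy)
    w1 = 1 - p1 / k1 - tv / (2 * gr)
    w2 = 1 - p2 / k2 - tv / (2 * gy)
    w3 = 1 - tv / (2 * gr * gy)
    d = -k1 * _safe_log(w1) - k2 * _safe_log(w2) - k3 * _safe_log(w3)
    return max(0.0, d) if math.isfinite(d) else math.inf


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(np.diag(self.matrix), 0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(self.matrix, self.matrix.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        if (self.matrix[np.isfinite(self.matrix)] < 0).any():
            raise ValueError("distances must be non-negative")

    @property
    def has_infinite(self) -> bool:
        return bool(~np.isfinite(self.matrix).all())


def distance_matrix(rows: list[str], taxa: list[str], model: str = "K80") -> DistanceMatrix:
    n = len(taxa)
    codes = [encode(r.upper()) for r in rows]
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            # reuse distance() on raw strings for clarity; n is small here
            m[i, j] = m[j, i] = _distance_from_codes(codes[i], codes[j], model)
    return DistanceMatrix(taxa=list(taxa), matrix=m)


def _distance_from_codes(a, b, model):
    n, p, ts, tv, p1, p2, f = _pair_counts(a, b)
    if model == "p":
        return p
    if model == "JC69":
        return max(0.0, -0.75 * _safe_log(1 - 4 * p / 3))
    if model == "K80":
        return max(0.0, -0.5 * _safe_log(1 - 2 * ts - tv) - 0.25 * _safe_log(1 - 2 * tv))
    pa, pc, pg, pt = f
    if min(pa, pc, pg, pt) <= 0:
        return _distance_from_codes(a, b, "K80")
    gr, gy = pa + pg, pc + pt
    k1 = 2 * pa * pg / gr
    k2 = 2 * pc * pt / gy
    k3 = 2 * (gr * gy - pa * pg * gy / gr - pc * pt * gr / gy)
    d = (-k1 * _safe_log(1 - p1 / k1 - tv / (2 * gr))
         - k2 * _safe_log(1 - p2 / k2 - tv / (2 * gy))
         - k3 * _safe_log(1 - tv / (2 * gr * gy)))
    return max(0.0, d) if math.isfinite(d) else math.inf


class _Cluster:
    __slots__ = ("newick",)

    def __init__(self, newick: str):
        self.newick = newick


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Standard neighbor joining.

    Deterministic: ties in the Q criterion are broken by the lowest index
    pair in current working order.  Negative branch-length estimates are
    clamped to zero (the clamped deficit is discarded; distances here are
    estimates, not path lengths).
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    if dm.has_infinite:
        raise ValueError(
            "distance matrix contains infinite (saturated) entries; "
            "use a different model or remove the offending taxa"
        )
    D = dm.matrix.copy()
    nodes = [_Cluster(t) for t in dm.taxa]

    def _bl(x: float) -> str:
        return f"{max(0.0, x):.10g}"

    while len(nodes) > 3:
        m = len(nodes)
        tot = D.sum(axis=1)
        Q = (m - 2) * D - tot[:, None] - tot[None, :]
        np.fill_diagonal(Q, np.inf)
        best = (np.inf, None)
        for i in range(m):
            for j in range(i + 1, m):
                if Q[i, j] < best[0] - 1e-12:
                    best = (Q[i, j], (i, j))
        i, j = best[1]
        li = 0.5 * D[i, j] + (tot[i] - tot[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        new = _Cluster(f"({nodes[i].newick}:{_bl(li)},{nodes[j].newick}:{_bl(lj)})")
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [new]
        D = D2

    # final three clusters joined at an unrooted central node
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = 0.5 * (d01 + d02 - d12)
    l1 = 0.5 * (d01 + d12 - d02)
    l2 = 0.5 * (d02 + d12 - d01)
    newick = (f"({nodes[0].newick}:{_bl(l0)},{nodes[1].newick}:{_bl(l1)},"
              f"{nodes[2].newick}:{_bl(l2)});")
    return parse_newick(newick)


def nj_tree(sm_rows: list[str], taxa: list[str], model: str = "K80") -> dendropy.Tree:
    """Convenience: distance matrix + NJ in one call."""
    return neighbor_joining(distance_matrix(sm_rows, taxa, model))


def bootstrap_support(sm: Supermatrix, model: str = "K80",
                      replicates: int = 100, seed: int = 0) -> dendropy.Tree:
    """NJ tree on the full matrix, internal edges annotated with bootstrap
    support (percentage of column-resampled replicates containing the
    bipartition)."""
    if replicates < 1:
        raise ValueError("replicates >= 1 required")
    from .trees import bipartitions, leaf_labels

    base = nj_tree(sm.rows, sm.taxa, model)
    counts: dict[frozenset, int] = {bp: 0 for bp in bipartitions(base)}
    rng = np.random.default_rng(seed)
    arr = sm.as_array()
    for _ in range(replicates):
        idx = rng.integers(0, sm.width, size=sm.width)
        rows = ["".join(r) for r in arr[:, idx]]
        rep = nj_tree(rows, sm.taxa, model)
        for bp in bipartitions(rep):
            if bp in counts:
                counts[bp] += 1
    full = frozenset(leaf_labels(base))
    anchor = sorted(full)[0]
    for node in base.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = full - side
        if side in counts:
            node.label = f"{100.0 * counts[side] / replicates:g}"
    return base


@dataclass
class GeneAuditRow:
    gene: str
    length: int
    single_tree: dendropy.Tree
    single_rf: int
    single_type: str | None
    jackknife_tree: dendropy.Tree | None
    jackknife_rf: int | None
    jackknife_type: str | None
    flagged: str | None = None  # "insufficient signal" / "jackknife undefined"


@dataclass
class GeneAuditReport:
    consensus: dendropy.Tree
    model: str
    rows: list[GeneAuditRow] = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd

        recs = []
        for r in self.rows:
            recs.append({
                "gene": r.gene, "length": r.length,
                "single_topology": r.single_type or "-",
                "single_RF": r.single_rf,
                "jackknife_topology": (r.jackknife_type or "-") if r.jackknife_tree else "-",
                "jackknife_RF": r.jackknife_rf if r.jackknife_rf is not None else "",
                "flag": r.flagged or "",
            })
        return pd.DataFrame(recs)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def gene_audit(sm: Supermatrix, consensus: dendropy.Tree, model: str = "K80",
               name_map=None, classify: bool = True,
               min_partition_length: int = 150) -> GeneAuditReport:
    """Per-gene influence audit: a tree from each partition alone, a tree
    from everything but that partition, RF distances of both to the
    consensus, and (optionally) the five-taxon topology type of each."""
    report = GeneAuditReport(consensus=consensus, model=model)
    genes = sm.gene_order()
    for gene in genes:
        s, e = sm.partition_map[gene]
        length = e - s
        flag = "insufficient signal" if length < min_partition_length else None
        sub = sm.gene_slice(gene)
        single = nj_tree(sub.rows, sub.taxa, model)
        single_rf = rf_distance(single, consensus)
        single_type = _maybe_classify(single, name_map) if classify else None
        if len(genes) > 1:
            rest = sm.exclude_gene(gene)
            jack = nj_tree(rest.rows, rest.taxa, model)
            jack_rf = rf_distance(jack, consensus)
            jack_type = _maybe_classify(jack, name_map) if classify else None
        else:
            jack, jack_rf, jack_type = None, None, None
            flag = (flag + "; " if flag else "") + "jackknife undefined"
        report.rows.append(GeneAuditRow(
            gene=gene, length=length, single_tree=single, single_rf=single_rf,
            single_type=single_type, jackknife_tree=jack, jackknife_rf=jack_rf,
            jackknife_type=jack_type, flagged=flag,
        ))
    return report


def _maybe_classify(tree, name_map):
    try:
        return classify_arborophila(tree, name_map)
    except ValueError:
        return None
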