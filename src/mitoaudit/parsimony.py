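"""Exact parsimony machinery: Fitch small-parsimony scoring, exhaustive
enumeration of unrooted binary topologies, and exact Bremer / partitioned
Bremer support (PBS) on small taxon sets.

Bremer support of a clade is the number of extra parsimony steps required
by the best tree *lacking* that clade; PBS decomposes it per data partition,
and the partition contributions sum to the clade's Bremer value by
construction.  Everything here is exact: trees are enumerated exhaustively
(the count is (2n-5)!!, so n is capped), which keeps the support values
free of search heuristics.  PBS values are integers under the parsimony
definition implemented here; likelihood-based variants produce fractional
values and are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import dendropy

from .supermatrix import Supermatrix
from .trees import parse_newick

MAX_ENUM_TAXA = 8

_MASK = {"A": 1, "C": 2, "G": 4, "T": 8}
_MISSING = 15  # gaps and ambiguity codes are treated as fully missing


def double_factorial_trees(n: int) -> int:
    """Number of unrooted binary topologies on n labelled leaves: (2n-5)!!."""
    out = 1
    for k in range(3, 2 * n - 4, 2):
        out *= k
    return out


# Unrooted trees are represented internally as nested tuples over leaf
# indices, rooted at the node adjacent to leaf 0: the full tree is the edge
# {leaf 0, structure}.  Leaves are ints, internal nodes are 2-tuples.

def _enumerate_structures(n: int) -> Iterator[tuple]:
    """All rooted shapes over leaves 1..n-1 (i.e. all unrooted trees on n)."""
    def insert_everywhere(struct, leaf):
        yield (struct, leaf)  # on the edge above `struct` (incl. leaf-0 edge)
        if isinstance(struct, tuple):
            left, right = struct
            for s in insert_everywhere(left, leaf):
                yield (s, right)
            for s in insert_everywhere(right, leaf):
                yield (left, s)

    def build(k, struct):
        if k == n:
            yield struct
            return
        for s in insert_everywhere(struct, k):
            yield from build(k + 1, s)

    if n == 3:
        yield (1, 2)
        return
    yield from build(3, (1, 2))


def _structure_to_newick(struct, taxa: list[str]) -> str:
    def render(s):
        if isinstance(s, int):
            return taxa[s]
        return f"({render(s[0])},{render(s[1])})"

    if isinstance(struct, tuple):
        return f"({taxa[0]},{render(struct[0])},{render(struct[1])});"
    return f"({taxa[0]},{render(struct)});"


def _structure_clades(struct, n: int) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of leaf indices on the side
    away from leaf 0."""
    out = set()

    def walk(s) -> frozenset:
        if isinstance(s, int):
            return frozenset([s])
        left, right = walk(s[0]), walk(s[1])
        clade = left | right
        if 2 <= len(clade) <= n - 2:
            out.add(clade)
        return clade

    walk(struct)
    return out


def enumerate_trees(taxa: list[str], max_n: int = MAX_ENUM_TAXA) -> Iterator[dendropy.Tree]:
    """Stream every distinct unrooted binary topology on the given taxa."""
    n = len(taxa)
    if n < 4:
        raise ValueError("need >= 4 taxa")
    if n > max_n:
        raise ValueError(
            f"{n} taxa gives {double_factorial_trees(n)} topologies; refusing "
            f"exhaustive enumeration beyond {max_n} taxa"
        )
    for struct in _enumerate_structures(n):
        yield parse_newick(_structure_to_newick(struct, taxa))


def _column_masks(sm: Supermatrix, taxa_order: list[str]) -> np.ndarray:
    """(n_taxa, width) uint8 state-set masks in the given taxon order."""
    idx = [sm.taxa.index(t) for t in taxa_order]
    arr = np.empty((len(taxa_order), sm.width), dtype=np.uint8)
    for row_out, row_in in enumerate(idx):
        s = sm.rows[row_in]
        arr[row_out] = [
            _MASK.get(c, _MISSING) for c in s
        ]
    return arr


def _fitch_changes(struct, masks: np.ndarray) -> np.ndarray:
    """Per-column Fitch change counts for the unrooted tree rooted at leaf 0."""
    changes = np.zeros(masks.shape[1], dtype=np.int64)

    def fitch(s) -> np.ndarray:
        if isinstance(s, int):
            return masks[s]
        a, b = fitch(s[0]), fitch(s[1])
        inter = a & b
        empty = inter == 0
        changes[empty] += 1
        return np.where(empty, a | b, inter)

    root_set = fitch(struct)
    # unite with leaf 0 across the root edge
    empty = (root_set & masks[0]) == 0
    changes[empty] += 1
    return changes


@dataclass
class ParsimonyScore:
    tree: dendropy.Tree
    total: int
    per_partition: dict[str, int]


def fitch_score(tree: dendropy.Tree, sm: Supermatrix) -> ParsimonyScore:
    """Fitch parsimony score of a binary tree on the supermatrix, with
    per-partition subtotals.  Gaps and ambiguity codes are missing data."""
    from .trees import leaf_labels

    labels = leaf_labels(tree)
    if set(labels) != set(sm.taxa):
        raise ValueError(
            f"tree/matrix taxon mismatch: {sorted(set(labels) ^ set(sm.taxa))}"
        )
    struct, order = _tree_to_structure(tree)
    masks = _column_masks(sm, order)
    changes = _fitch_changes(struct, masks)
    per = {g: int(changes[s:e].sum()) for g, (s, e) in sm.partition_map.items()}
    return ParsimonyScore(tree=tree, total=int(changes.sum()), per_partition=per)


def _tree_to_structure(tree: dendropy.Tree):
    """Convert a (possibly rooted) binary dendropy tree into the internal
    rooted-at-first-leaf structure plus the taxon order used for indices."""
    work = tree.clone(depth=1)
    work.deroot()  # unroot: basal trifurcation
    leaves = [lf.taxon.label for lf in work.leaf_node_iter()]
    order = sorted(leaves)
    index = {lab: i for i, lab in enumerate(order)}
    anchor = order[0]
    node0 = work.find_node_with_taxon_label(anchor)
    work.reroot_at_edge(node0.edge, update_bipartitions=False)

    def convert(node):
        kids = [c for c in node.child_nodes()]
        if not kids:
            return index[node.taxon.label]
        if len(kids) == 1:
            return convert(kids[0])
        sub = convert(kids[0])
        for k in kids[1:]:
            sub = (sub, convert(k))
        return sub

    root_kids = [c for c in work.seed_node.child_nodes()]
    subs = []
    for c in root_kids:
        if c.is_leaf() and c.taxon.label == anchor:
            continue
        subs.append(convert(c))
    struct = subs[0]
    for s in subs[1:]:
        struct = (struct, s)
    return struct, order


@dataclass
class SupportReport:
    clade: frozenset
    bremer: int
    pbs: dict[str, int]
    best_tree: str
    best_score: int
    best_antagonist: str
    best_antagonist_score: int

    def to_tsv_row(self) -> str:
        genes = sorted(self.pbs)
        return "\t".join(
            [",".join(sorted(self.clade)), str(self.bremer)]
            + [str(self.pbs[g]) for g in genes]
        )


def bremer_and_pbs(sm: Supermatrix, clade: Iterable[str],
                   max_n: int = MAX_ENUM_TAXA) -> SupportReport:
    """Exact Bremer and partitioned Bremer support for one clade.

    ``clade`` is one side of a leaf bipartition.  All unrooted binary trees
    on the matrix taxa are enumerated; ``best`` is the minimum-score tree
    overall and ``best_anti`` the minimum-score tree lacking the clade.
    Ties are broken by the lexicographically smallest Newick string, which
    makes the reported per-partition decomposition deterministic; the
    identity sum(PBS) == Bremer holds for any tie choice.
    """
    taxa = sorted(sm.taxa)
    n = len(taxa)
    if n < 4:
        raise ValueError("need >= 4 taxa")
    if n > max_n:
        raise ValueError(
            f"{n} taxa gives {double_factorial_trees(n)} topologies; refusing "
            f"exhaustive enumeration beyond {max_n} taxa"
        )
    index = {t: i for i, t in enumerate(taxa)}
    clade = frozenset(clade)
    unknown = clade - set(taxa)
    if unknown:
        raise ValueError(f"clade taxa not in matrix: {sorted(unknown)}")
    if not (2 <= len(clade) <= n - 2):
        raise ValueError(
            "clade must be a non-trivial bipartition side "
            f"(2..{n - 2} taxa, got {len(clade)})"
        )
    target = frozenset(index[t] for t in clade)
    if 0 in target:
        target = frozenset(range(n)) - target

    masks_full = _column_masks(sm, taxa)
    # only parsimony-relevant columns can change the score differences
    informative = np.array([
        len({m for m in masks_full[:, j] if m != _MISSING}) > 1
        for j in range(masks_full.shape[1])
    ])
    cols = np.flatnonzero(informative)
    masks = masks_full[:, cols]
    part_of_col = np.empty(len(cols), dtype=np.int32)
    genes = sm.gene_order()
    for gi, g in enumerate(genes):
        s, e = sm.partition_map[g]
        part_of_col[(cols >= s) & (cols < e)] = gi

    best = None          # (total, newick, per_partition)
    best_anti = None
    for struct in _enumerate_structures(n):
        changes = _fitch_changes(struct, masks)
        total = int(changes.sum())
        contains = target in _structure_clades(struct, n)
        candidate = None
        if best is None or total < best[0]:
            candidate = True
        if candidate or (total == best[0]):
            newick = _structure_to_newick(struct, taxa)
            if best is None or total < best[0] or (total == best[0] and newick < best[1]):
                per = np.bincount(part_of_col, weights=changes, minlength=len(genes))
                best = (total, newick, per.astype(int))
        if not contains:
            if best_anti is None or total < best_anti[0]:
                newick = _structure_to_newick(struct, taxa)
                per = np.bincount(part_of_col, weights=changes, minlength=len(genes))
                best_anti = (total, newick, per.astype(int))
            elif total == best_anti[0]:
                newick = _structure_to_newick(struct, taxa)
                if newick < best_anti[1]:
                    per = np.bincount(part_of_col, weights=changes, minlength=len(genes))
                    best_anti = (total, newick, per.astype(int))
    if best_anti is None:
        raise ValueError("every enumerated tree contains the clade; support undefined")
    pbs = {g: int(best_anti[2][gi] - best[2][gi]) for gi, g in enumerate(genes)}
    return SupportReport(
        clade=clade, bremer=best_anti[0] - best[0], pbs=pbs,
        best_tree=best[1], best_score=best[0],
        best_antagonist=best_anti[1], best_antagonist_score=best_anti[0],
    )
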