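"""Test-side utilities: random tree generation and independent oracles.

These deliberately avoid the implementation paths they are used to check.
"""

from __future__ import annotations

import numpy as np
import dendropy

from mitoaudit.parsimony import _structure_to_newick


def random_structure(n: int, rng) -> tuple:
    """Uniform-ish random unrooted binary topology on n leaves as the nested
    rooted-at-leaf-0 tuple representation (leaves are ints 1..n-1)."""
    struct = (1, 2)

    def positions(s):
        yield ()
        if isinstance(s, tuple):
            for i, sub in enumerate(s):
                for p in positions(sub):
                    yield (i,) + p

    def insert(s, path, leaf):
        if not path:
            return (s, leaf)
        head, *rest = path
        parts = list(s)
        parts[head] = insert(parts[head], tuple(rest), leaf)
        return tuple(parts)

    for leaf in range(3, n):
        pos = list(positions(struct))
        struct = insert(struct, pos[rng.integers(0, len(pos))], leaf)
    return struct


def random_newick(n: int, rng, prefix: str = "t",
                  lengths: bool = False) -> str:
    taxa = [f"{prefix}{i}" for i in range(n)]
    nwk = _structure_to_newick(random_structure(n, rng), taxa)
    if lengths:
        tree = dendropy.Tree.get(data=nwk, schema="newick",
                                 preserve_underscores=True)
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node:
                edge.length = float(rng.uniform(0.05, 1.0))
        nwk = tree.as_string(schema="newick", suppress_rooting=True).strip()
    return nwk


def dendropy_rf(nwk1: str, nwk2: str) -> int:
    """Independent Robinson-Foulds oracle via dendropy's bipartition machinery."""
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=nwk1, schema="newick", taxon_namespace=tns,
                           preserve_underscores=True)
    t2 = dendropy.Tree.get(data=nwk2, schema="newick", taxon_namespace=tns,
                           preserve_underscores=True)
    return int(dendropy.calculate.treecompare.symmetric_difference(t1, t2))


def patristic_matrix(nwk: str) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path-length (additive) distance matrix of a tree."""
    tree = dendropy.Tree.get(data=nwk, schema="newick",
                             preserve_underscores=True)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(taxa)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return labels, m


def brute_force_fitch(tree_nwk: str, columns: list[dict]) -> int:
    """Exact small-parsimony score by exhaustive minimization over all
    internal-state assignments (independent of the Fitch implementation).

    ``columns`` is a list of {taxon: base} mappings; missing taxa or
    non-ACGT states contribute no cost constraint (treated as free).
    """
    tree = dendropy.Tree.get(data=tree_nwk, schema="newick",
                             preserve_underscores=True)
    tree.deroot()
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    leaves = [nd for nd in tree.leaf_node_iter()]
    edges = []
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            edges.append((nd.parent_node, nd))
    total = 0
    import itertools

    for col in columns:
        best = None
        leaf_state = {}
        free_leaves = []
        for lf in leaves:
            b = col.get(lf.taxon.label)
            if b in ("A", "C", "G", "T"):
                leaf_state[id(lf)] = "ACGT".index(b)
            else:
                free_leaves.append(lf)
        for assign in itertools.product(range(4), repeat=len(internals) + len(free_leaves)):
            states = dict(leaf_state)
            for nd, s in zip(internals, assign[:len(internals)]):
                states[id(nd)] = s
            for lf, s in zip(free_leaves, assign[len(internals):]):
                states[id(lf)] = s
            cost = sum(states[id(a)] != states[id(b)] for a, b in edges)
            if best is None or cost < best:
                best = cost
        total += best
    return total
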