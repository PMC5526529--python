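"""Tree utilities: Newick I/O, Robinson-Foulds distance, induced subtrees,
and classification of the five-species hill-partridge clade topology.

Trees are held as :class:`dendropy.Tree` objects.  Robinson-Foulds distances
are computed on unrooted bipartitions even for rooted inputs, matching the
convention of the standard R implementations.  Polytomies are allowed: only
bipartitions actually present are counted, so non-binary trees can yield odd
distances.

The five-taxon topology classification is the one subtle operation here.  As
*unrooted* five-leaf trees, the two competing arrangements ("type I" and
"type II") share both cherries ({ardens, brunneopectus} and
{gingica, rufogularis}) and differ only in the rooted position of
*rufipectus*; they are therefore distinguished on the *rooted* restriction,
using the attachment to the rest of the tree as the root direction.
"""

from __future__ import annotations

import io
from typing import Iterable, Mapping

import dendropy

#: Canonical labels for the five hill-partridge species.
ARBOROPHILA_TAXA = ("ardens", "brunneopectus", "rufipectus", "gingica", "rufogularis")

#: Rooted cluster sets defining the two competing arrangements.
TYPE_I_CLUSTERS = frozenset({
    frozenset({"ardens", "brunneopectus"}),
    frozenset({"ardens", "brunneopectus", "rufipectus"}),
    frozenset({"gingica", "rufogularis"}),
})
TYPE_II_CLUSTERS = frozenset({
    frozenset({"gingica", "rufogularis"}),
    frozenset({"gingica", "rufogularis", "rufipectus"}),
    frozenset({"ardens", "brunneopectus"}),
})

#: Literal Newick forms of the two arrangements (rooted, cherry-first).
TYPE_I_NEWICK = "(((ardens,brunneopectus),rufipectus),(gingica,rufogularis));"
TYPE_II_NEWICK = "(((gingica,rufogularis),rufipectus),(ardens,brunneopectus));"


class NewickError(ValueError):
    pass


def parse_newick(text: str) -> dendropy.Tree:
    """Parse one Newick tree; support values stored as internal labels are kept.

    Raises :class:`NewickError` on malformed input or duplicate leaf labels.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # noqa: BLE001
        raise NewickError(f"cannot parse Newick: {exc}") from exc
    labels = leaf_labels(tree)
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise NewickError(f"duplicate leaf labels: {dupes}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    out = tree.as_string(schema="newick", suppress_rooting=True,
                         unquoted_underscores=True)
    return out.strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def support_of(node: dendropy.Node) -> float | None:
    """Support value of an internal node, from the label-as-support dialect."""
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial unrooted bipartitions, each canonicalized as the side
    *not* containing the lexicographically smallest leaf label."""
    labels = sorted(leaf_labels(tree))
    anchor = labels[0]
    full = frozenset(labels)
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = full - side
        if 2 <= len(side) <= len(full) - 2:
            out.add(side)
    return out


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance: size of the symmetric difference of the
    non-trivial unrooted bipartition sets.  Leaf sets must match."""
    l1, l2 = set(leaf_labels(t1)), set(leaf_labels(t2))
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only-in-first={sorted(l1 - l2)} "
            f"only-in-second={sorted(l2 - l1)}"
        )
    return len(bipartitions(t1) ^ bipartitions(t2))


def restrict_to_taxa(tree: dendropy.Tree, taxa: Iterable[str]) -> dendropy.Tree:
    """Induced subtree on a taxon subset, with degree-2 nodes suppressed and
    branch lengths summed across suppressed nodes."""
    taxa = set(taxa)
    present = set(leaf_labels(tree))
    missing = taxa - present
    if missing:
        raise ValueError(f"taxa not in tree: {sorted(missing)}")
    if len(taxa) < 3:
        raise ValueError("need >= 3 taxa to induce a topology")
    sub = tree.extract_tree_with_taxa_labels(labels=taxa)
    sub.suppress_unifurcations()
    return sub


def _rooted_clusters(tree: dendropy.Tree, targets: set[str],
                     relabel: Mapping[str, str]) -> set[frozenset]:
    """Intersections of the tree's rooted clusters with the target taxa,
    relabelled to canonical names; sizes 2..len(targets)-1 only."""
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        clade = {lf.taxon.label for lf in node.leaf_iter()}
        inter = frozenset(relabel[x] for x in clade & targets)
        if 2 <= len(inter) <= len(targets) - 1:
            out.add(inter)
    return out


def classify_arborophila(tree: dendropy.Tree,
                         name_map: Mapping[str, str] | None = None) -> str:
    """Classify the five-species clade topology as ``type_I``, ``type_II``
    or ``other``.

    ``name_map`` maps tree leaf labels to the canonical species names in
    :data:`ARBOROPHILA_TAXA`; by default, a leaf label matches a canonical
    name if it contains it as a (case-insensitive) substring.

    Trees with more than five leaves are first rooted on the
    lexicographically smallest non-target leaf (the attachment to the rest
    of the tree supplies the root direction); a five-leaf input is read as
    rooted exactly as written.
    """
    labels = leaf_labels(tree)
    if name_map is None:
        name_map = {}
        for lab in labels:
            for canon in ARBOROPHILA_TAXA:
                if canon in lab.lower():
                    name_map[lab] = canon
    mapped = {lab: sp for lab, sp in name_map.items() if lab in labels}
    found = set(mapped.values())
    missing = set(ARBOROPHILA_TAXA) - found
    if missing:
        raise ValueError(f"target taxa absent from tree: {sorted(missing)}")
    targets = set(mapped)

    work = tree.clone(depth=1)
    if len(labels) > len(targets):
        outgroup = sorted(set(labels) - targets)[0]
        node = work.find_node_with_taxon_label(outgroup)
        work.reroot_at_edge(node.edge, update_bipartitions=False)
    clusters = _rooted_clusters(work, targets, mapped)
    if clusters == TYPE_I_CLUSTERS:
        return "type_I"
    if clusters == TYPE_II_CLUSTERS:
        return "type_II"
    return "other"


def distance_matrix_tsv(trees: Mapping[str, dendropy.Tree]) -> str:
    """Pairwise RF distance matrix over named trees, as TSV text."""
    names = list(trees)
    lines = ["\t" + "\t".join(names)]
    for a in names:
        cells = [str(rf_distance(trees[a], trees[b])) for b in names]
        lines.append(a + "\t" + "\t".join(cells))
    return "\n".join(lines) + "\n"
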