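"""Fitch scoring, exhaustive topology enumeration, Bremer and PBS."""

import pytest

from helpers import brute_force_fitch, random_newick

from mitoaudit.parsimony import (bremer_and_pbs, double_factorial_trees,
                                 enumerate_trees, fitch_score)
from mitoaudit.supermatrix import Supermatrix
from mitoaudit.trees import bipartitions, parse_newick


def make_sm(rows, taxa, partitions=None):
    if partitions is None:
        partitions = {"g": (0, len(rows[0]))}
    return Supermatrix(taxa=list(taxa), rows=list(rows),
                       partition_map=partitions)


class TestEnumerateTrees:
    @pytest.mark.parametrize("n,count", [(4, 3), (5, 15), (6, 105), (8, 10395)])
    def test_double_factorial_counts(self, n, count):
        taxa = [f"t{i}" for i in range(n)]
        trees = list(enumerate_trees(taxa))
        assert len(trees) == count == double_factorial_trees(n)

    def test_no_duplicate_topologies(self):
        taxa = [f"t{i}" for i in range(6)]
        seen = {frozenset(bipartitions(t)) for t in enumerate_trees(taxa)}
        assert len(seen) == 105

    def test_refuses_combinatorial_explosion(self):
        with pytest.raises(ValueError, match="refusing"):
            list(enumerate_trees([f"t{i}" for i in range(9)]))


class TestFitchScore:
    def test_constant_column_zero(self):
        sm = make_sm(["A", "A", "A", "A"], "abcd")
        t = parse_newick("((a,b),(c,d));")
        assert fitch_score(t, sm).total == 0

    def test_textbook_four_taxon_case(self):
        """AABB needs 1 change on the matching tree, 2 on the conflicting."""
        sm = make_sm(["A", "A", "C", "C"], ["a1", "a2", "b1", "b2"])
        match = parse_newick("((a1,a2),(b1,b2));")
        conflict = parse_newick("((a1,b1),(a2,b2));")
        assert fitch_score(match, sm).total == 1
        assert fitch_score(conflict, sm).total == 2

    def test_ambiguity_treated_as_missing(self):
        sm = make_sm(["AN", "A-", "CR", "CN"], "abcd")
        t = parse_newick("((a,b),(c,d));")
        # column 1: A/A/C/C -> 1; column 2: all missing -> 0
        assert fitch_score(t, sm).total == 1

    def test_matches_exhaustive_minimization(self, rng):
        """Fitch equals brute-force minimization over internal states on
        random instances (n <= 6, columns <= 20)."""
        for _ in range(30):
            n = int(rng.integers(4, 7))
            taxa = [f"t{i}" for i in range(n)]
            nwk = random_newick(n, rng)
            ncols = int(rng.integers(3, 21))
            arr = rng.choice(list("ACGTN-"), size=(n, ncols),
                             p=[.22, .22, .22, .22, .06, .06])
            sm = make_sm(["".join(r) for r in arr], taxa)
            cols = [{taxa[i]: arr[i, j] for i in range(n)}
                    for j in range(ncols)]
            assert fitch_score(parse_newick(nwk), sm).total == \
                brute_force_fitch(nwk, cols)

    def test_invariant_to_column_permutation_and_relabeling(self, rng):
        n, ncols = 6, 30
        taxa = [f"t{i}" for i in range(n)]
        arr = rng.choice(list("ACGT"), size=(n, ncols))
        nwk = random_newick(n, rng)
        sm = make_sm(["".join(r) for r in arr], taxa)
        base = fitch_score(parse_newick(nwk), sm).total
        perm = rng.permutation(ncols)
        sm_p = make_sm(["".join(r[perm]) for r in arr], taxa)
        assert fitch_score(parse_newick(nwk), sm_p).total == base
        # consistent relabeling of matrix and tree
        relabel = {t: f"x{t}" for t in taxa}
        nwk_r = nwk
        for old, new in sorted(relabel.items(), reverse=True):
            nwk_r = nwk_r.replace(old, new)
        sm_r = make_sm(["".join(r) for r in arr], [relabel[t] for t in taxa])
        assert fitch_score(parse_newick(nwk_r), sm_r).total == base

    def test_per_partition_subtotals_sum(self, benchmark):
        sm = benchmark.supermatrix
        from mitoaudit.infer import nj_tree

        score = fitch_score(nj_tree(sm.rows, sm.taxa), sm)
        assert sum(score.per_partition.values()) == score.total

    def test_taxon_mismatch_raises(self):
        sm = make_sm(["A", "A", "C", "C"], "abcd")
        with pytest.raises(ValueError, match="mismatch"):
            fitch_score(parse_newick("((a,b),(c,e));"), sm)


class TestBremerAndPBS:
    def test_single_partition_pbs_equals_bremer(self, rng):
        n = 5
        taxa = [f"t{i}" for i in range(n)]
        arr = rng.choice(list("ACGT"), size=(n, 40))
        sm = make_sm(["".join(r) for r in arr], taxa)
        rep = bremer_and_pbs(sm, ("t0", "t1"))
        assert rep.pbs == {"g": rep.bremer}

    def test_two_conflicting_partitions_hand_case(self):
        """Two partitions supporting conflicting 5-taxon splits.

        Partition g1 has 6 binary characters grouping {a,b}; g2 has 4
        grouping {b,c}.  A 2-vs-3 binary character costs 1 step on a tree
        containing its split and 2 otherwise, so the best tree (score 14)
        contains {a,b}, the best antagonist (score 16) contains {b,c}:
        Bremer({a,b}) = 2 with PBS (+6, -4) — hand enumeration over the
        15 five-taxon topologies."""
        col_ab = ["T", "T", "A", "A", "A"]   # a,b vs c,d,e
        col_bc = ["A", "T", "T", "A", "A"]   # b,c vs a,d,e
        rows = ["".join(col_ab[i] * 6 + col_bc[i] * 4) for i in range(5)]
        sm = make_sm(rows, "abcde",
                     partitions={"g1": (0, 6), "g2": (6, 10)})
        rep = bremer_and_pbs(sm, ("a", "b"))
        assert rep.bremer == 2
        assert rep.pbs == {"g1": 6, "g2": -4}
        assert rep.best_score == 14
        assert rep.best_antagonist_score == 16

    def test_sum_identity_on_benchmark_clades(self, benchmark):
        """sum(PBS) == Bremer for every internal clade of the consensus."""
        from mitoaudit.infer import nj_tree

        sm = benchmark.supermatrix
        consensus = nj_tree(sm.rows, sm.taxa)
        for clade in bipartitions(consensus):
            rep = bremer_and_pbs(sm, clade)
            assert sum(rep.pbs.values()) == rep.bremer
            assert rep.bremer >= 0

    def test_dominant_partition_largest_pbs_at_focal_clade(self, benchmark):
        """The conflicting ND5-like partition carries the largest |PBS| at
        the disputed grouping, with opposite sign to the rest."""
        sm = benchmark.supermatrix
        rep = bremer_and_pbs(sm, ("ardens", "brunneopectus", "rufipectus"))
        biggest = max(rep.pbs, key=lambda g: abs(rep.pbs[g]))
        assert biggest == "ND5"
        assert rep.pbs["ND5"] > 0
        assert sum(rep.pbs.values()) == rep.bremer

    def test_bremer_zero_iff_optimal_tree_lacks_clade(self, rng):
        """When the best tree does not contain the queried clade, the best
        antagonistic tree IS the best tree and Bremer is exactly 0."""
        # strong signal for {a,b}: query the conflicting clade {b,c}
        col_ab = ["T", "T", "A", "A", "A"]
        rows = ["".join(col_ab[i] * 10) for i in range(5)]
        sm = make_sm(rows, "abcde")
        rep = bremer_and_pbs(sm, ("b", "c"))
        assert rep.bremer == 0
        assert rep.best_antagonist_score == rep.best_score

    def test_trivial_clade_rejected(self, benchmark):
        sm = benchmark.supermatrix
        with pytest.raises(ValueError, match="non-trivial"):
            bremer_and_pbs(sm, ("ardens",))
        with pytest.raises(ValueError, match="not in matrix"):
            bremer_and_pbs(sm, ("ardens", "nosuch"))
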