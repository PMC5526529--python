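"""Closed-form distances, neighbor joining, bootstrap and the gene audit."""

import math

import numpy as np
import pytest

from helpers import patristic_matrix, random_newick

from mitoaudit.infer import (DistanceMatrix, bootstrap_support, distance,
                             gene_audit, neighbor_joining, nj_tree)
from mitoaudit.supermatrix import GeneAlignment, concatenate
from mitoaudit.trees import (classify_arborophila, parse_newick,
                             rf_distance, write_newick)
from mitoaudit.simulate import (GTRParams, PartitionConfig, SimConfig,
                                simulate_alignment)


class TestDistance:
    @pytest.mark.parametrize("model", ["p", "JC69", "K80", "TN93"])
    def test_identical_sequences_zero(self, model):
        assert distance("ACGTACGTAC", "ACGTACGTAC", model) == 0.0

    def test_jc69_saturation_flagged_not_raised(self):
        # p = 0.75 sits exactly on the JC69 divergence boundary
        a = "A" * 100
        b = ("C" * 25) + ("G" * 25) + ("T" * 25) + ("A" * 25)
        assert distance(a, b, "JC69") == math.inf

    def test_sites_with_gaps_excluded(self):
        d = distance("ACGT-N", "ACGAAN", "p")
        assert d == pytest.approx(1 / 4)  # only 4 comparable sites, 1 diff

    def test_k80_recovery_from_simulation(self):
        """K80 distance estimate within 0.01 of the generating branch length
        at 100 kb (two-taxon tree, homogeneous rates, kappa=4)."""
        cfg = SimConfig(
            tree="(A:0.15,B:0.15);",
            partitions=[PartitionConfig("g", 100_000,
                                        invariant_codon_pos1=False)],
            gtr=GTRParams(exchangeabilities=(1, 4, 1, 1, 4, 1),
                          base_frequencies=(0.25, 0.25, 0.25, 0.25)),
            gamma_alpha=None, p_invariant=0.0, seed=7,
        )
        sm, _ = simulate_alignment(cfg)
        d = distance(sm.rows[0], sm.rows[1], "K80")
        assert d == pytest.approx(0.30, abs=0.01)

    def test_tn93_close_to_k80_under_equal_freqs(self):
        cfg = SimConfig(
            tree="(A:0.1,B:0.1);",
            partitions=[PartitionConfig("g", 50_000,
                                        invariant_codon_pos1=False)],
            gtr=GTRParams(exchangeabilities=(1, 4, 1, 1, 4, 1),
                          base_frequencies=(0.25, 0.25, 0.25, 0.25)),
            gamma_alpha=None, p_invariant=0.0, seed=8,
        )
        sm, _ = simulate_alignment(cfg)
        k80 = distance(sm.rows[0], sm.rows[1], "K80")
        tn93 = distance(sm.rows[0], sm.rows[1], "TN93")
        assert tn93 == pytest.approx(k80, abs=0.01)


class TestNeighborJoining:
    def test_three_taxa_star_solved(self):
        dm = DistanceMatrix(["a", "b", "c"],
                            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]]))
        tree = neighbor_joining(dm)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_four_taxon_additive_recovery(self):
        """Exact topology and branch lengths from an additive matrix."""
        nwk = "((a:1,b:2):3,(c:4,d:5):0);"
        labels, m = patristic_matrix(nwk)
        tree = neighbor_joining(DistanceMatrix(labels, m))
        assert rf_distance(tree, parse_newick(nwk)) == 0
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1, "b": 2, "c": 4, "d": 5})

    def test_consistency_on_random_additive_trees(self, rng):
        """NJ recovers the generating topology from noise-free additive
        distances (1000 random trees, n <= 10)."""
        for _ in range(1000):
            n = int(rng.integers(4, 11))
            nwk = random_newick(n, rng, lengths=True)
            labels, m = patristic_matrix(nwk)
            tree = neighbor_joining(DistanceMatrix(labels, m))
            assert rf_distance(tree, parse_newick(nwk)) == 0

    def test_infinite_entries_rejected(self):
        m = np.array([[0, 1, np.inf], [1, 0, 1], [np.inf, 1, 0.0]])
        with pytest.raises(ValueError, match="model"):
            neighbor_joining(DistanceMatrix(["a", "b", "c"], m))

    def test_tie_break_deterministic(self):
        """Equidistant matrices resolve identically on repeat runs."""
        m = np.ones((5, 5)) - np.eye(5)
        dm = DistanceMatrix(list("abcde"), m)
        t1, t2 = neighbor_joining(dm), neighbor_joining(dm)
        assert write_newick(t1) == write_newick(t2)

    def test_negative_branch_clamped(self):
        m = np.array([[0, 10, 1, 10], [10, 0, 10, 2],
                      [1, 10, 0, 10], [10, 2, 10, 0.0]])
        tree = neighbor_joining(DistanceMatrix(list("abcd"), m))
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0


class TestBootstrap:
    @staticmethod
    def _toy_sm(rng, length=2000):
        cfg = SimConfig(
            tree="((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1,(e:0.1,f:0.1):0.1);",
            partitions=[PartitionConfig("g", length,
                                        invariant_codon_pos1=False)],
            gamma_alpha=None, p_invariant=0.0, seed=int(rng.integers(1 << 30)),
        )
        sm, _ = simulate_alignment(cfg)
        return sm, cfg.tree

    def test_single_replicate_supports_binary(self, rng):
        sm, _ = self._toy_sm(rng, 500)
        tree = bootstrap_support(sm, replicates=1, seed=0)
        sups = [float(nd.label) for nd in tree.preorder_node_iter()
                if not nd.is_leaf() and nd.label]
        assert sups and set(sups) <= {0.0, 100.0}

    def test_clean_data_high_support(self, rng):
        """Long, well-separated branches: every true bipartition >= 95."""
        sm, true_nwk = self._toy_sm(rng, 4000)
        tree = bootstrap_support(sm, replicates=100, seed=3)
        assert rf_distance(tree, parse_newick(true_nwk)) == 0
        sups = [float(nd.label) for nd in tree.preorder_node_iter()
                if not nd.is_leaf() and nd.label]
        assert min(sups) >= 95

    def test_seed_determinism(self, rng):
        sm, _ = self._toy_sm(rng, 800)
        t1 = bootstrap_support(sm, replicates=25, seed=11)
        t2 = bootstrap_support(sm, replicates=25, seed=11)
        assert write_newick(t1) == write_newick(t2)


class TestGeneAudit:
    def test_no_conflict_all_rf_zero(self):
        """All partitions simulated on one topology: every single-gene and
        jackknife tree matches the consensus."""
        tree = "((a:0.08,b:0.08):0.08,(c:0.08,d:0.08):0.08,(e:0.08,f:0.08):0.08);"
        cfg = SimConfig(
            tree=tree,
            partitions=[PartitionConfig(f"g{i}", 1500,
                                        invariant_codon_pos1=False)
                        for i in range(4)],
            gamma_alpha=None, p_invariant=0.0, seed=5,
        )
        sm, _ = simulate_alignment(cfg)
        consensus = nj_tree(sm.rows, sm.taxa)
        report = gene_audit(sm, consensus, classify=False)
        assert all(r.single_rf == 0 for r in report.rows)
        assert all(r.jackknife_rf == 0 for r in report.rows)

    def test_single_partition_jackknife_flagged(self):
        rows = ["ACGTAC" * 50, "ACGTAT" * 50, "ACCTAC" * 50, "AGGTAC" * 50]
        sm = concatenate([GeneAlignment("only", list("abcd"), rows)])
        consensus = nj_tree(sm.rows, sm.taxa)
        report = gene_audit(sm, consensus, classify=False,
                            min_partition_length=150)
        (row,) = report.rows
        assert row.jackknife_tree is None
        assert "jackknife undefined" in row.flagged

    def test_short_partition_flagged_not_dropped(self, benchmark):
        sm = benchmark.supermatrix
        consensus = nj_tree(sm.rows, sm.taxa)
        report = gene_audit(sm, consensus, min_partition_length=200)
        by_gene = {r.gene: r for r in report.rows}
        assert by_gene["ATP8"].flagged == "insufficient signal"
        assert len(report.rows) == 13

    def test_benchmark_nd5_conflict_phenomenon(self, benchmark):
        """The planted dominant conflicting partition: its single-gene tree
        matches its override topology, and it is the only gene whose
        exclusion flips the five-taxon topology type of the jackknife tree."""
        sm = benchmark.supermatrix
        consensus = nj_tree(sm.rows, sm.taxa)
        assert classify_arborophila(consensus) == "type_I"
        report = gene_audit(sm, consensus)
        by_gene = {r.gene: r for r in report.rows}
        assert by_gene["ND5"].single_type == "type_I"
        assert by_gene["ND5"].jackknife_type == "type_II"
        for gene, row in by_gene.items():
            if gene != "ND5":
                assert row.jackknife_type == "type_I"
        # the conflicting gene is also the farthest jackknife from consensus
        assert by_gene["ND5"].jackknife_rf == max(r.jackknife_rf
                                                  for r in report.rows)

    def test_report_dataframe_shape(self, benchmark):
        sm = benchmark.supermatrix
        consensus = nj_tree(sm.rows, sm.taxa)
        df = gene_audit(sm, consensus).to_dataframe()
        assert list(df.columns) == ["gene", "length", "single_topology",
                                    "single_RF", "jackknife_topology",
                                    "jackknife_RF", "flag"]
        assert list(df.gene) == sm.gene_order()
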