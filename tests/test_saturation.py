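"""Transition/transversion profiles and the entropy saturation index."""

import numpy as np
import pytest
from scipy.linalg import expm

from mitoaudit.saturation import (full_saturation_entropy, iss, iss_critical,
                                  iss_subsampled, pairwise_profiles,
                                  saturation_test)
from mitoaudit.supermatrix import Supermatrix
from mitoaudit.simulate import (GTRParams, PartitionConfig, SimConfig,
                                benchmark_config, saturation_ladder,
                                simulate_alignment)

BASES = np.array(list("ACGT"))


def sm_from_rows(rows, taxa=None):
    taxa = taxa or [f"t{i}" for i in range(len(rows))]
    return Supermatrix(taxa=taxa, rows=rows,
                       partition_map={"g": (0, len(rows[0]))})


class TestPairwiseProfiles:
    def test_single_transition(self):
        rows = ["A" * 100, "G" + "A" * 99]
        (p,) = pairwise_profiles(sm_from_rows(rows))
        assert p.proportion_transitions == pytest.approx(0.01)
        assert p.proportion_transversions == 0
        assert p.p_distance == pytest.approx(0.01)

    def test_identical_sequences_zero_profile(self):
        (p,) = pairwise_profiles(sm_from_rows(["ACGT" * 25] * 2))
        assert (p.p_distance, p.proportion_transitions,
                p.proportion_transversions) == (0, 0, 0)

    def test_transitions_plus_transversions_equal_p(self, benchmark):
        for p in pairwise_profiles(benchmark.supermatrix):
            assert p.proportion_transitions + p.proportion_transversions == \
                pytest.approx(p.p_distance)

    def test_codon_position_selector(self, benchmark):
        """First codon positions are invariant in the simulated CDSs, so
        their profiles are all-zero while third positions vary."""
        pos1 = pairwise_profiles(benchmark.supermatrix, "pos1")
        assert all(p.p_distance == 0 for p in pos1)
        pos3 = pairwise_profiles(benchmark.supermatrix, "pos3")
        assert max(p.p_distance for p in pos3) > 0

    def test_bad_selector(self, benchmark):
        with pytest.raises(ValueError):
            pairwise_profiles(benchmark.supermatrix, "pos4")

    def test_k80_closed_form_oracle(self):
        """Observed transition/transversion proportions at a known K80
        branch length match the matrix-exponential expectation."""
        kappa, t = 4.0, 0.4
        cfg = SimConfig(
            tree=f"(A:{t/2},B:{t/2});",
            partitions=[PartitionConfig("g", 200_000,
                                        invariant_codon_pos1=False)],
            gtr=GTRParams(exchangeabilities=(1, kappa, 1, 1, kappa, 1),
                          base_frequencies=(0.25,) * 4),
            gamma_alpha=None, p_invariant=0.0, seed=42,
        )
        sm, _ = simulate_alignment(cfg)
        (prof,) = pairwise_profiles(sm)
        Q = cfg.gtr.rate_matrix()
        P = expm(Q * t)
        # A<->G and C<->T are transitions under the ACGT state order
        exp_ts = 0.25 * (2 * P[0, 2] + 2 * P[1, 3])
        exp_tv = 0.25 * (P.sum() - np.trace(P)) - exp_ts
        assert prof.proportion_transitions == pytest.approx(exp_ts, abs=0.004)
        assert prof.proportion_transversions == pytest.approx(exp_tv, abs=0.004)


class TestIss:
    def test_monomorphic_alignment_is_zero(self):
        with pytest.warns(UserWarning, match="invariant"):
            assert iss(["ACGT" * 100] * 5) == 0.0

    def test_random_alignment_near_one(self, rng):
        rows = ["".join(BASES[rng.integers(0, 4, 6000)]) for _ in range(7)]
        assert iss(rows) == pytest.approx(1.0, abs=0.02)

    def test_binary_column_entropy_formula(self):
        """A two-state k/(n-k) column contributes exactly the binary
        entropy H(k/n)."""
        n, k = 8, 3
        rows = ["A" if i < k else "C" for i in range(n)]
        value = iss([r for r in rows], base_freqs=[0.25] * 4)
        h = -(k / n) * np.log2(k / n) - ((n - k) / n) * np.log2((n - k) / n)
        assert value == pytest.approx(h / full_saturation_entropy(n, [0.25] * 4))

    def test_invariant_to_taxon_and_column_order(self, rng):
        rows = ["".join(BASES[rng.integers(0, 4, 400)]) for _ in range(6)]
        base = iss(rows)
        assert iss(rows[::-1]) == pytest.approx(base)
        perm = rng.permutation(400)
        assert iss(["".join(np.array(list(r))[perm]) for r in rows]) == \
            pytest.approx(base)

    def test_monotone_under_progressive_randomization(self, rng):
        """Randomizing a growing fraction of columns never decreases Iss."""
        cfg = SimConfig(
            tree="((a:0.02,b:0.02):0.02,(c:0.02,d:0.02):0.02,(e:0.02,f:0.02):0.02);",
            partitions=[PartitionConfig("g", 6000, invariant_codon_pos1=False)],
            gamma_alpha=None, p_invariant=0.0, seed=3,
        )
        sm, _ = simulate_alignment(cfg)
        arr = sm.as_array()
        values = []
        for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
            scrambled = arr.copy()
            k = int(frac * arr.shape[1])
            scrambled[:, :k] = BASES[rng.integers(0, 4, size=(arr.shape[0], k))]
            values.append(iss(["".join(r) for r in scrambled]))
        assert all(b >= a - 0.01 for a, b in zip(values, values[1:]))
        assert values[0] < 0.2 and values[-1] > 0.95

    def test_subsampled_average(self, benchmark):
        v = iss_subsampled(benchmark.supermatrix, 4, draws=5, seed=0)
        assert 0 < v < 1


class TestIssCritical:
    def test_reproducible_and_finite(self):
        a = iss_critical(n_otus=4, seq_length=400, replicates=120, seed=9)
        b = iss_critical(n_otus=4, seq_length=400, replicates=120, seed=9)
        assert a.iss_c == b.iss_c
        assert 0 < a.iss_c <= 1.001

    def test_low_replicates_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            iss_critical(n_otus=4, seq_length=200, replicates=60, seed=0)

    def test_recovery_degrades_along_ladder(self):
        crit = iss_critical(n_otus=4, seq_length=400, replicates=120, seed=2)
        assert crit.recovery_by_step[0] > crit.recovery_by_step[-1]
        assert crit.recovery_by_step[-1] < 0.95


class TestSaturationDecision:
    def test_fully_saturated_input(self, rng):
        rows = ["".join(BASES[rng.integers(0, 4, 3000)]) for _ in range(7)]
        res = saturation_test(sm_from_rows(rows), replicates=120, seed=1)
        assert res.decision == "substantial-saturation"

    def test_shallow_divergence_little_saturation(self, benchmark):
        res = saturation_test(benchmark.supermatrix, replicates=120, seed=1)
        assert res.decision == "little-saturation"
        assert res.iss < res.iss_c
        assert res.p_value < 0.001


class TestSaturationLadder:
    def test_monotone_and_limits(self):
        cfg = benchmark_config(seed=4)
        cfg.partitions = cfg.partitions[:3]  # keep the ladder light
        cfg.gamma_alpha = 10.0
        sms = saturation_ladder(cfg, steps=4, scales=[0.0, 0.3, 3.0, 60.0])
        values = []
        for sm in sms:
            with np.errstate(all="ignore"):
                import warnings as w

                with w.catch_warnings():
                    w.simplefilter("ignore")
                    values.append(iss(sm))
        assert values[0] == 0.0          # zero-length branches: no variation
        assert values[-1] == pytest.approx(1.0, abs=0.02)  # saturation limit
        assert all(b >= a - 0.01 for a, b in zip(values, values[1:]))
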