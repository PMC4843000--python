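"""Threshold network: wiring statistics, propagation, NDP, dynamic range."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from dentate.network import (
    DGNetwork,
    NetworkConfig,
    SweepConfig,
    build_network,
    dynamic_range,
    ec_sweep,
    mean_pairwise_ndp,
    ndp,
    neurogenesis_sweep,
    propagate,
    sample_ec_pattern,
)

binary_vec = st.lists(st.integers(0, 1), min_size=1, max_size=40)


def hand_network(rows, threshold_frac=0.20):
    """Small explicit network from 0/1 rows (one row per GC)."""
    W = np.array(rows, dtype=bool)
    return DGNetwork(
        weights=W, immature=np.zeros(W.shape[0], dtype=bool),
        threshold_frac=threshold_frac,
    )


class TestBuildNetwork:
    def test_complete_and_empty_graphs(self):
        full = build_network(
            NetworkConfig(n_ec=50, n_gc=30, conn_prob_mature=1.0,
                          conn_prob_immature=1.0, frac_immature=0.5)
        )
        assert (full.in_degree == 50).all()
        empty = build_network(
            NetworkConfig(n_ec=50, n_gc=30, conn_prob_mature=0.0,
                          conn_prob_immature=0.0, frac_immature=0.5)
        )
        assert (empty.in_degree == 0).all()

    def test_default_in_degrees_match_binomial_expectation(self):
        net = build_network(NetworkConfig(frac_immature=0.5, seed=3))
        mature_deg = net.in_degree[~net.immature]
        imm_deg = net.in_degree[net.immature]
        for deg, p in ((mature_deg, 219 / 1296), (imm_deg, 77 / 1296)):
            expected = 1300 * p
            sem = np.sqrt(1300 * p * (1 - p)) / np.sqrt(deg.size)
            assert abs(deg.mean() - expected) < 2 * sem
        assert imm_deg.mean() < mature_deg.mean()

    def test_immature_count_rounding(self):
        net = build_network(NetworkConfig(n_ec=20, n_gc=1000, frac_immature=0.123))
        assert net.immature.sum() == 123

    def test_fixed_in_degree_option(self):
        net = build_network(
            NetworkConfig(n_ec=100, n_gc=40, conn_prob_mature=0.3,
                          conn_prob_immature=0.1, frac_immature=0.5,
                          fixed_in_degree=True)
        )
        assert (net.in_degree[net.immature] == 10).all()
        assert (net.in_degree[~net.immature] == 30).all()

    def test_seed_determinism(self):
        a = build_network(NetworkConfig(n_ec=80, n_gc=60, seed=9))
        b = build_network(NetworkConfig(n_ec=80, n_gc=60, seed=9))
        assert np.array_equal(a.weights, b.weights)

    def test_rejects_empty_population(self):
        with pytest.raises(ValueError):
            NetworkConfig(n_ec=0, n_gc=10)


class TestSampleEcPattern:
    @pytest.mark.parametrize("level, expected", [(0.0, 0), (1.0, 1300), (0.10, 130)])
    def test_exact_counts(self, level, expected, rng):
        pattern = sample_ec_pattern(1300, level, rng)
        assert pattern.sum() == expected
        assert set(np.unique(pattern)) <= {0, 1}

    def test_rejects_bad_level(self, rng):
        with pytest.raises(ValueError):
            sample_ec_pattern(100, 1.5, rng)


class TestPropagate:
    def test_zero_input_zero_output(self):
        net = build_network(NetworkConfig(n_ec=40, n_gc=20, seed=0))
        assert propagate(net, np.zeros(40, dtype=np.int8)).sum() == 0

    def test_strict_threshold(self):
        # one GC wired to the first 10 of 12 EC cells, threshold 20% -> needs > 2
        net = hand_network([[1] * 10 + [0] * 2])
        three = np.zeros(12, dtype=np.int8)
        three[:3] = 1
        assert propagate(net, three)[0] == 1
        two = np.zeros(12, dtype=np.int8)
        two[:2] = 1
        assert propagate(net, two)[0] == 0

    def test_zero_in_degree_never_fires(self):
        net = hand_network([[0, 0, 0]])
        assert propagate(net, np.ones(3, dtype=np.int8))[0] == 0

    def test_rejects_length_mismatch(self):
        net = hand_network([[1, 0, 1]])
        with pytest.raises(ValueError):
            propagate(net, np.ones(4, dtype=np.int8))

    def test_exhaustive_toy_network_oracle(self):
        """5-EC/4-GC network checked against plain-loop hand computation for
        all 32 EC patterns."""
        rows = [
            [1, 1, 1, 1, 1],
            [1, 1, 0, 0, 0],
            [0, 0, 0, 1, 1],
            [0, 1, 1, 1, 0],
        ]
        net = hand_network(rows, threshold_frac=0.4)
        for bits in range(32):
            ec = np.array([(bits >> i) & 1 for i in range(5)], dtype=np.int8)
            got = propagate(net, ec)
            for g, row in enumerate(rows):
                active_inputs = sum(r * e for r, e in zip(row, ec))
                expected = 1 if active_inputs > 0.4 * sum(row) else 0
                assert got[g] == expected, f"pattern {bits}, gc {g}"

    def test_mean_activity_increases_with_drive(self):
        net = build_network(NetworkConfig(seed=5))
        rng = np.random.default_rng(0)
        act = {}
        for level in (0.10, 0.22):
            outs = []
            for _ in range(20):
                outs.append(propagate(net, sample_ec_pattern(1300, level, rng)).mean())
            act[level] = np.mean(outs)
        assert act[0.22] > act[0.10]

    def test_immature_recruited_before_mature(self):
        """At EC drive below the mature threshold, the active fraction of
        immature GCs exceeds that of mature GCs in a mixed network."""
        net = build_network(NetworkConfig(frac_immature=0.5, seed=8))
        rng = np.random.default_rng(1)
        imm, mat = [], []
        for _ in range(10):
            out = propagate(net, sample_ec_pattern(1300, 0.13, rng))
            imm.append(out[net.immature].mean())
            mat.append(out[~net.immature].mean())
        assert np.mean(imm) >= np.mean(mat)


class TestNdp:
    def test_examples(self):
        assert ndp([1, 1, 0], [1, 0, 1]) == pytest.approx(0.5)
        assert ndp([1, 0], [0, 1]) == 0.0
        assert ndp([0, 0], [1, 1]) == 0.0  # all-zero defined as 0

    @given(x=binary_vec)
    def test_self_similarity(self, x):
        expected = 1.0 if any(x) else 0.0
        assert ndp(x, x) == pytest.approx(expected)

    @given(x=binary_vec, data=st.data())
    def test_bounds_and_symmetry(self, x, data):
        y = data.draw(st.lists(st.integers(0, 1), min_size=len(x), max_size=len(x)))
        v = ndp(x, y)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(ndp(y, x))

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            ndp([1, 0], [1, 0, 1])


class TestMeanPairwiseNdp:
    def test_identical_outputs(self):
        A = np.ones((10, 5), dtype=np.int8)
        assert mean_pairwise_ndp(A) == pytest.approx(1.0)

    def test_disjoint_outputs(self):
        A = np.eye(4, dtype=np.int8)
        assert mean_pairwise_ndp(A) == pytest.approx(0.0)

    def test_accepts_pattern_list(self):
        assert mean_pairwise_ndp([[1, 1, 0], [1, 0, 1]]) == pytest.approx(0.5)

    def test_rejects_single_output(self):
        with pytest.raises(ValueError):
            mean_pairwise_ndp(np.ones((10, 1)))

    def test_sampling_noise_between_seeds(self):
        """Two independent input draws on one network give mean NDP within 0.01."""
        net = build_network(NetworkConfig(seed=2))
        a = ec_sweep(net, (0.16,), 100, np.random.default_rng(0))["mean_ndp"][0]
        b = ec_sweep(net, (0.16,), 100, np.random.default_rng(1))["mean_ndp"][0]
        assert abs(a - b) < 0.01


class TestEcSweep:
    def test_silent_below_threshold_and_saturated_at_full_drive(self):
        net = build_network(NetworkConfig(n_ec=200, n_gc=400, seed=4))
        curve = ec_sweep(net, (0.001, 1.0), 20, np.random.default_rng(0))
        assert curve["mean_ndp"][0] == 0.0  # no GC reaches threshold
        assert curve["mean_ndp"][1] == pytest.approx(1.0)  # identical outputs

    def test_stochastic_monotonicity(self):
        """Mean NDP never drops by more than sampling noise between adjacent
        EC levels."""
        net = build_network(NetworkConfig(seed=6))
        levels = tuple(np.round(0.10 + 0.01 * np.arange(13), 10))
        curve = ec_sweep(net, levels, 50, np.random.default_rng(3))
        diffs = np.diff(curve["mean_ndp"])
        assert (diffs > -0.005).all()


class TestDynamicRange:
    LEVELS = (0.10, 0.12, 0.14, 0.16, 0.18)

    def test_direct_subtraction(self):
        values = (0.0, 0.005, 0.01, 0.05, 0.9)
        assert dynamic_range(self.LEVELS, values) == pytest.approx(0.04)

    def test_flat_zero(self):
        assert dynamic_range(self.LEVELS, (0.0,) * 5) == 0.0

    def test_step_curve(self):
        assert dynamic_range(self.LEVELS, (0, 0, 1.0, 1.0, 1.0)) == 0.0

    def test_high_never_reached(self):
        values = (0.0, 0.006, 0.01, 0.02, 0.03)
        assert dynamic_range(self.LEVELS, values) == pytest.approx(0.18 - 0.12)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            dynamic_range((), ())


class TestNeurogenesisSweep:
    SMALL_NET = NetworkConfig(n_ec=260, n_gc=1000)
    SMALL_SWEEP = SweepConfig(
        ec_levels=tuple(np.round(0.10 + 0.02 * np.arange(7), 10)),
        ng_levels=(0.0, 0.5, 1.0),
        n_input_sets=10,
        n_runs=2,
        seed=17,
    )

    def test_reproducible_and_complete(self):
        a = neurogenesis_sweep(self.SMALL_NET, self.SMALL_SWEEP)
        b = neurogenesis_sweep(self.SMALL_NET, self.SMALL_SWEEP)
        pd.testing.assert_frame_equal(a.ndp, b.ndp)
        pd.testing.assert_frame_equal(a.ranges, b.ranges)
        assert len(a.ranges) == 3 * 2
        assert a.ndp["mean_ndp"].between(0, 1).all()
        assert (a.ranges["dynamic_range"] >= 0).all()
        summary = a.summary()
        assert set(summary) == {
            "argmax_ng_level",
            "max_mean_range",
            "mean_range_at_ng0",
            "range_ratio_vs_ng0",
        }

    def test_parallel_matches_serial(self):
        serial = neurogenesis_sweep(self.SMALL_NET, self.SMALL_SWEEP, n_jobs=1)
        parallel = neurogenesis_sweep(self.SMALL_NET, self.SMALL_SWEEP, n_jobs=2)
        pd.testing.assert_frame_equal(serial.ranges, parallel.ranges)

    def test_immature_curve_rises_earlier_and_shallower(self):
        """A fully immature network reaches nonzero NDP at lower EC drive and
        with a smaller maximal slope than a fully mature one."""
        levels = tuple(np.round(0.10 + 0.005 * np.arange(25), 10))
        rng = np.random.default_rng(0)
        mature = ec_sweep(
            build_network(NetworkConfig(frac_immature=0.0, seed=1)), levels, 30, rng
        )
        immature = ec_sweep(
            build_network(NetworkConfig(frac_immature=1.0, seed=1)), levels, 30, rng
        )
        first_nonzero = lambda c: c.loc[c["mean_ndp"] >= 0.005, "ec_level"].iloc[0]
        assert first_nonzero(immature) < first_nonzero(mature)
        assert np.diff(immature["mean_ndp"]).max() < np.diff(mature["mean_ndp"]).max()
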