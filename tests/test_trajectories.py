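"""Trajectory-shape statistics: shortest half, PSD/MPS, crookedness."""

import numpy as np
import pandas as pd
import pytest

from prsvar.exceptions import InsufficientDataError
from prsvar.params import SimulationParams
from prsvar.simulate import simulate_trajectories
from prsvar.trajectories import (
    TrajectorySet,
    classify_crooked,
    crookedness_index,
    mps,
    progressive_spread,
    shortest_half_width,
)


def brute_shortest_half(values):
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    h = int(np.ceil(n / 2))
    return min(x[i + h - 1] - x[i] for i in range(n - h + 1))


def constant_in_time_set(col, n_t=5):
    """Same per-cell values at every timepoint."""
    col = np.asarray(col, dtype=float)
    return TrajectorySet(
        times=np.arange(n_t, dtype=float) + 1.0, P=np.tile(col[:, None], (1, n_t))
    )


class TestShortestHalf:
    def test_integer_grid_oracle(self):
        # any 5 consecutive of {0..9} span 4
        assert shortest_half_width(np.arange(10.0)) == 4.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for n in (4, 5, 17, 100):
            x = rng.normal(size=n)
            assert shortest_half_width(x) == pytest.approx(
                brute_shortest_half(x), rel=1e-12
            )

    def test_bounded_by_range(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(size=200)
        assert shortest_half_width(x) <= x.max() - x.min()

    def test_approximates_iqr_for_symmetric_samples(self):
        x = np.random.default_rng(2).standard_normal(50_000)
        iqr = np.quantile(x, 0.75) - np.quantile(x, 0.25)
        assert shortest_half_width(x) == pytest.approx(iqr, rel=0.05)


class TestCrookednessIndex:
    def test_monotone_is_zero(self):
        assert crookedness_index([0, 1, 2, 3]) == 0.0

    def test_hand_oracle(self):
        # increments (2, -1, 2): net 3, total 5 -> 0.4
        assert crookedness_index([0, 2, 1, 3]) == pytest.approx(0.4, rel=1e-12)

    def test_constant_trajectory_degenerate_rule(self):
        assert crookedness_index([2, 2, 2]) == 0.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        assert crookedness_index(3.7 * x + 11) == pytest.approx(
            crookedness_index(x), rel=1e-12
        )

    def test_range(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            v = crookedness_index(rng.normal(size=10))
            assert 0.0 <= v <= 1.0

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            crookedness_index([1, 2])


class TestProgressiveSpread:
    def test_identical_trajectories_zero_spread(self):
        tset = TrajectorySet(times=[1.0, 2.0, 3.0], P=np.ones((6, 3)))
        _, spreads = progressive_spread(tset, onset_index=0)
        np.testing.assert_allclose(spreads, 0.0)

    def test_time_constant_population(self):
        col = np.array([0.5, 0.9, 1.0, 1.1, 1.5, 2.0])
        tset = constant_in_time_set(col)
        _, spreads = progressive_spread(tset, onset_index=0)
        expected = shortest_half_width(col / np.median(col))
        np.testing.assert_allclose(spreads, expected)

    def test_relabeling_and_scaling_invariance(self):
        rng = np.random.default_rng(5)
        P = rng.uniform(0.5, 2.0, size=(20, 4))
        tset = TrajectorySet(times=np.arange(4.0) + 1, P=P)
        _, s1 = progressive_spread(tset, onset_index=0)
        shuffled = TrajectorySet(times=tset.times, P=P[rng.permutation(20)])
        _, s2 = progressive_spread(shuffled, onset_index=0)
        scaled = TrajectorySet(times=tset.times, P=7.3 * P)
        _, s3 = progressive_spread(scaled, onset_index=0)
        np.testing.assert_allclose(s1, s2)
        np.testing.assert_allclose(s1, s3, rtol=1e-12)


class TestMPS:
    def test_identical_trajectories(self):
        tset = TrajectorySet(times=[1.0, 2.0, 3.0], P=np.full((5, 3), 2.0))
        res = mps(tset, n_boot=200, seed=0)
        assert res.mps == 0.0
        assert (res.ci_low, res.ci_high) == (0.0, 0.0)

    def test_time_constant_population_equals_single_timepoint_width(self):
        col = np.array([0.5, 0.9, 1.0, 1.1, 1.5, 2.0])
        tset = constant_in_time_set(col)
        res = mps(tset, n_boot=200, seed=0, onset_index=0)
        assert res.mps == pytest.approx(shortest_half_width(col / np.median(col)))

    def test_ci_calibration_against_sampling_distribution(self):
        # The shortest-half width carries a systematic small-sample
        # downward bias (cube-root asymptotics), so the CI is checked
        # against the estimator's own sampling distribution at this n,
        # not against the large-n limit.
        p = SimulationParams(lambda_mode="relative", seed=0)
        times = np.arange(0.0, 301.0, 30.0)
        runs = 30
        results = []
        for s in range(runs):
            small, _ = simulate_trajectories(p.replace(seed=100 + s), 120, times)
            results.append(mps(small, n_boot=300, seed=s))
        center = float(np.median([r.mps for r in results]))
        hits = sum(r.ci_low <= center <= r.ci_high for r in results)
        assert hits / runs >= 0.8
        for r in results:
            assert r.ci_low <= r.mps <= r.ci_high

    def test_n_boot_validation(self):
        tset = TrajectorySet(times=[1.0, 2.0], P=np.ones((4, 2)))
        with pytest.raises(InsufficientDataError):
            mps(tset, n_boot=1)


class TestClassifyCrooked:
    def test_monotone_set_has_zero_crooked_fraction(self):
        P = np.cumsum(np.ones((8, 5)), axis=1)
        tset = TrajectorySet(times=np.arange(5.0) + 1, P=P)
        _, summary = classify_crooked(tset)
        assert summary["crooked_fraction"] == 0.0

    def test_threshold_one_flags_nothing(self):
        rng = np.random.default_rng(6)
        tset = TrajectorySet(times=np.arange(6.0) + 1, P=rng.uniform(size=(30, 6)))
        _, summary = classify_crooked(tset, threshold=1.0)
        assert summary["crooked_fraction"] == 0.0

    def test_injected_fraction_recovered(self):
        # strong transient excursions, low pathway noise
        p = SimulationParams(eta2_lambda=0.0005, lambda_mode="relative", seed=4)
        times = np.arange(0.0, 181.0, 30.0)
        tset, truth = simulate_trajectories(
            p, 200, times, crooked_frac=0.15, jump_magnitude=8.0
        )
        _, summary = classify_crooked(tset)
        injected = truth["crooked"].mean()
        band = 3 * np.sqrt(injected * (1 - injected) / len(truth))
        assert abs(summary["crooked_fraction"] - injected) <= band

    def test_below_mean_classification(self):
        # two crooked cells: one ends low, one ends high
        P = np.array(
            [
                [0.0, 1.0, 2.0, 3.0],
                [0.0, 3.0, 0.5, 0.6],
                [0.0, 0.2, 4.0, 9.0],
            ]
        )
        tset = TrajectorySet(times=np.arange(4.0) + 1, P=P)
        per_cell, summary = classify_crooked(tset, threshold=0.3)
        assert per_cell["crooked"].tolist() == [False, True, False]
        assert summary["crooked_below_mean_fraction"] == 1.0
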