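"""Generator contracts: determinism, degenerate cases, self-consistency."""

import numpy as np
import pandas as pd
import pytest

from prsvar.decomposition import decompose_population
from prsvar.exceptions import ParameterError
from prsvar.params import SimulationParams
from prsvar.simulate import simulate_population, simulate_screen, simulate_trajectories
from prsvar.trajectories import classify_crooked, crookedness_index


class TestParams:
    def test_invalid_parameters_name_the_field(self):
        with pytest.raises(ParameterError, match="eta2_G"):
            SimulationParams(eta2_G=-0.1)
        with pytest.raises(ParameterError, match="EC50"):
            SimulationParams(EC50=0.0)
        with pytest.raises(ParameterError, match="rho"):
            SimulationParams(rho=1.5)
        with pytest.raises(ParameterError, match="nonresponder_frac"):
            SimulationParams(nonresponder_frac=2.0)

    def test_truncation_guard(self):
        # heavy absolute pathway noise at a near-basal dose would clip
        p = SimulationParams(eta2_lambda=0.01, lambda_mode="absolute")
        with pytest.raises(ParameterError, match="truncation"):
            p.check_truncation(0.1)

    def test_hill_curve_endpoints(self):
        p = SimulationParams()
        assert p.mean_capacity(0.0) == p.L_basal
        assert p.mean_capacity(p.EC50) == pytest.approx(
            p.L_basal + (p.Lbar_max - p.L_basal) / 2
        )

    def test_calibration_targets(self):
        p = SimulationParams(lambda_mode="relative")
        internals = p.noise_internals(20.0)
        a, q, v_g = internals.a, (internals.gamma_sd / p.Gbar) ** 2, internals.v_G
        assert 2 * q * (1 + a) == pytest.approx(p.eta2_gamma, rel=1e-10)
        assert v_g + q == pytest.approx(p.eta2_G, rel=1e-10)
        assert a * (1 + p.eta2_G) - a * p.eta2_gamma / (1 + a) == pytest.approx(
            p.expected_eta2_P(20.0), rel=1e-10
        )


class TestSimulatePopulation:
    def test_deterministic_given_seed(self, params):
        a = simulate_population(params, 500, 0.6, twin_inducible=True)
        b = simulate_population(params, 500, 0.6, twin_inducible=True)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_zero_noise_cells_identical(self):
        p = SimulationParams(eta2_L=0, eta2_lambda=0, eta2_G=0, eta2_gamma=0, rho=0)
        df = simulate_population(p, 100, 2.0)
        assert df["ind_r"].nunique() == 1
        assert df["con_y"].nunique() == 1

    def test_no_signal_without_capacity(self):
        p = SimulationParams(L_basal=0.0, eta2_lambda=0.0)
        df = simulate_population(p, 50, 0.0)
        assert (df["ind_r"] == 0).all()

    def test_monotone_dose_response(self, params):
        rng = np.random.default_rng(1)
        means = [
            simulate_population(params, 20_000, d, rng=rng)["ind_r"].mean()
            for d in (0.0, 0.3, 0.6, 2.0, 6.0, 20.0)
        ]
        assert all(m1 <= m2 for m1, m2 in zip(means, means[1:]))

    def test_estimator_self_consistency_improves_with_n(self):
        p = SimulationParams(
            eta2_G=0.04, rho=0.0, lambda_mode="relative", seed=17
        )
        errs = {}
        for n in (2_000, 200_000):
            d = decompose_population(simulate_population(p, n, 20.0))
            errs[n] = abs(d.eta2_G / p.eta2_G - 1)
        assert errs[200_000] < errs[2_000]
        assert errs[200_000] < 0.03

    def test_nonresponders_stay_basal(self):
        p = SimulationParams(nonresponder_frac=0.3, seed=9)
        df = simulate_population(p, 4_000, 20.0)
        assert df["nonresponder"].mean() == pytest.approx(0.3, abs=0.05)
        resp = df.loc[~df["nonresponder"], "ind_r"]
        non = df.loc[df["nonresponder"], "ind_r"]
        assert non.mean() < 0.1 * resp.mean()

    def test_n_cells_validation(self, params):
        with pytest.raises(ParameterError):
            simulate_population(params, 0, 0.6)


class TestSimulateTrajectories:
    TIMES = np.arange(0.0, 301.0, 30.0)

    def test_noiseless_trajectories_are_monotone_with_zero_crookedness(self):
        p = SimulationParams(eta2_lambda=0.0)
        tset, truth = simulate_trajectories(p, 30, self.TIMES, crooked_frac=0.0)
        assert not truth["crooked"].any()
        # cumulative inducible signal is nondecreasing: P transitions 0 -> level
        for row in tset.P:
            assert crookedness_index(row) == pytest.approx(0.0, abs=1e-12)

    def test_empty_collection(self, params):
        tset, truth = simulate_trajectories(params, 0, self.TIMES)
        assert tset.n_cells == 0 and truth.empty

    def test_injected_jumps_are_detected(self):
        # strong transient excursions, low pathway noise, short grid
        p = SimulationParams(eta2_lambda=0.0005, lambda_mode="relative", seed=4)
        times = np.arange(0.0, 181.0, 30.0)
        tset, truth = simulate_trajectories(
            p, 300, times, crooked_frac=1.0, jump_magnitude=8.0
        )
        per_cell, _ = classify_crooked(tset)
        detection = per_cell["crooked"].mean()
        # oracle: direct classification of the injected labels on the same seeds
        assert truth["crooked"].all()
        # late, downward excursions relax too little to cross the threshold,
        # so detection is high but not total
        assert detection > 0.7

    def test_crooked_frac_validation(self, params):
        with pytest.raises(ParameterError):
            simulate_trajectories(params, 10, self.TIMES, crooked_frac=1.5)
        with pytest.raises(ParameterError):
            simulate_trajectories(params, 10, [0.0, 30.0, 20.0])

    def test_determinism(self, params):
        a, _ = simulate_trajectories(params, 20, self.TIMES, crooked_frac=0.5)
        b, _ = simulate_trajectories(params, 20, self.TIMES, crooked_frac=0.5)
        np.testing.assert_array_equal(a.P, b.P)


class TestSimulateScreen:
    def test_minimal_screen_population_count(self, params):
        cells, truth = simulate_screen(params, 1, 1, 50, seed=0)
        pops = cells.groupby(["strain", "dose_nM", "replicate"]).ngroups
        assert pops == 2  # two doses
        assert len(truth) == 1

    def test_multiplier_validation(self, params):
        with pytest.raises(ParameterError):
            simulate_screen(params, 2, 1, 10, mean_multipliers=[1.0, -1.0], seed=0)

    def test_variability_effect_separates_from_mean_effect(self, params):
        # one strain with 4x pathway variability and unchanged mean output
        cells, truth = simulate_screen(
            params,
            2,
            1,
            40_000,
            mean_multipliers=[1.0, 1.0],
            var_multipliers=[1.0, 4.0],
            seed=7,
        )
        decomp = cells.groupby(["strain", "dose_nM"]).apply(
            lambda g: pd.Series(decompose_population(g).to_dict()),
            include_groups=False,
        )
        ref = decomp.loc[("strain_0000", 20.0)]
        var = decomp.loc[("strain_0001", 20.0)]
        assert var["eta2_P_plus_gamma"] > 2.5 * ref["eta2_P_plus_gamma"]
        assert var["O"] == pytest.approx(ref["O"], rel=0.03)

    def test_deterministic_given_seed(self, params):
        a, _ = simulate_screen(params, 3, 2, 30, seed=5)
        b, _ = simulate_screen(params, 3, 2, 30, seed=5)
        assert a.to_csv(index=False) == b.to_csv(index=False)
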