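"""Residuals, AIC, parameter estimation and model comparison."""

import warnings
from dataclasses import asdict

import numpy as np
import pytest

import cropgrowth as cg
from cropgrowth.fitting import FitSpec, fittable_parameters


class TestResiduals:
    def test_sign_convention_model_minus_observation(self):
        rs = cg.compute_residuals([1.0, 2.0, 3.0], [0.0, 2.0, 5.0])
        np.testing.assert_array_equal(rs.residuals, [1.0, 0.0, -2.0])

    def test_perfect_prediction_gives_zeros(self):
        rs = cg.compute_residuals([1.0, 2.0], [1.0, 2.0])
        np.testing.assert_array_equal(rs.residuals, [0.0, 0.0])

    def test_constant_offset(self):
        obs = np.arange(5.0)
        rs = cg.compute_residuals(obs + 1.0, obs)
        np.testing.assert_array_equal(rs.residuals, np.ones(5))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            cg.compute_residuals([1.0, 2.0], [1.0, 2.0, 3.0])


class TestAIC:
    def test_unit_variance_leaves_only_penalty(self):
        assert cg.aic(100.0, 100, 3) == pytest.approx(6.0)

    def test_hand_value(self):
        assert cg.aic(12.5, 50, 5) == pytest.approx(-59.3147, abs=1e-4)

    def test_strictly_increasing_in_ssr(self):
        assert cg.aic(50.0, 100, 3) < cg.aic(100.0, 100, 3)

    def test_literal_variant(self):
        assert cg.aic(12.5, 50, 5, literal=True) == pytest.approx(22.5)

    def test_zero_ssr_warns_and_returns_neg_inf(self):
        with pytest.warns(UserWarning):
            assert cg.aic(0.0, 10, 2) == -np.inf

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError):
            cg.aic(1.0, 3, 3)


class TestNormalizeBiomass:
    def test_division_by_1000(self):
        np.testing.assert_allclose(
            cg.normalize_biomass([1000.0, 0.0, 250.0]), [1.0, 0.0, 0.25]
        )

    def test_rescaling_does_not_move_estimates(self, logistic_trajectory):
        """Estimates in user units agree with rescaling on or off."""
        r_on = cg.fit_model(
            FitSpec("logistic", biomass_rescale=True),
            logistic_trajectory.t,
            logistic_trajectory.biomass,
        )
        r_off = cg.fit_model(
            FitSpec("logistic", biomass_rescale=False),
            logistic_trajectory.t,
            logistic_trajectory.biomass,
        )
        for name in r_on.estimates:
            assert r_on.estimates[name] == pytest.approx(
                r_off.estimates[name], rel=1e-4
            )


class TestFitSpec:
    def test_free_and_fixed_must_partition(self):
        with pytest.raises(ValueError, match="neither free nor fixed"):
            FitSpec("logistic", free=("growth_rate",))
        with pytest.raises(ValueError, match="both"):
            FitSpec(
                "logistic",
                free=("growth_rate", "carrying_capacity", "initial_biomass"),
                fixed={"growth_rate": 0.1},
            )
        with pytest.raises(ValueError, match="unknown"):
            FitSpec("logistic", free=("growth_rate", "hue"))

    def test_water_model_exposes_nine_parameters_plus_two_ics(self):
        names = fittable_parameters("water")
        assert len(names) == 11
        ics = {"initial_soil_water", "initial_biomass"}
        assert len(set(names) - ics) == 9
        assert ics <= set(names)
        assert FitSpec("water").k == 11

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            FitSpec("logistic", method="annealing")


class TestRecovery:
    def test_logistic_self_recovery(self, logistic_params, logistic_trajectory):
        result = cg.fit_model(
            FitSpec("logistic"),
            logistic_trajectory.t,
            logistic_trajectory.biomass,
        )
        truth = asdict(logistic_params)
        for name, value in result.estimates.items():
            assert value == pytest.approx(truth[name], rel=1e-3)
        assert result.converged

    def test_water_single_free_parameter_from_doubled_start(
        self, water_params, water_trajectory, rain_driver
    ):
        """Refitting one freed quantity of the soil-water model from a 2x
        start on noise-free data recovers the generating value."""
        name = "precip_conversion"
        truth = getattr(water_params, name)
        fixed = asdict(water_params)
        fixed.pop(name)
        result = cg.fit_model(
            FitSpec(
                "water", free=(name,), fixed=fixed, start={name: 2 * truth}
            ),
            water_trajectory.t,
            water_trajectory.biomass,
            soil_water_obs=water_trajectory.soil_water,
            drivers={"precipitation": rain_driver},
        )
        assert result.estimates[name] == pytest.approx(truth, rel=1e-3)

    def test_objective_invariance(self, logistic_trajectory):
        """Reported SSR equals an independent integrate->residual pass."""
        result = cg.fit_model(
            FitSpec("logistic"),
            logistic_trajectory.t,
            logistic_trajectory.biomass,
        )
        traj = cg.integrate_model(
            "logistic", result.params, logistic_trajectory.t
        )
        ssr = float(
            np.sum(
                ((traj.biomass - logistic_trajectory.biomass) / 1000.0) ** 2
            )
        )
        assert result.ssr == pytest.approx(ssr, rel=1e-6, abs=1e-30)

    def test_unidentifiable_spec_rejected(self, logistic_trajectory):
        with pytest.raises(ValueError, match="nidentifiable"):
            cg.fit_model(
                FitSpec("logistic"),
                logistic_trajectory.t[:3],
                logistic_trajectory.biomass[:3],
            )

    def test_nelder_mead_also_recovers(self, logistic_params, logistic_trajectory):
        result = cg.fit_model(
            FitSpec("logistic", method="nelder-mead"),
            logistic_trajectory.t,
            logistic_trajectory.biomass,
        )
        truth = asdict(logistic_params)
        for name, value in result.estimates.items():
            assert value == pytest.approx(truth[name], rel=1e-2)


class TestPseudoSearch:
    def test_single_candidate(self):
        theta, trace = cg.pseudo_search(
            lambda th: float(th @ th), [(-1, 1), (-1, 1)], 1, seed=3
        )
        assert len(trace) == 1 and theta.shape == (2,)

    def test_deterministic_under_seed(self):
        obj = lambda th: float(th @ th)
        a, _ = cg.pseudo_search(obj, [(-2, 2)] * 3, 32, seed=11)
        b, _ = cg.pseudo_search(obj, [(-2, 2)] * 3, 32, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_unbounded_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            cg.pseudo_search(lambda th: 0.0, [(0, np.inf)], 4, seed=0)

    def test_pseudo_polish_escapes_bad_start(self, logistic_params):
        """With a deliberately bad default start, the Latin-hypercube
        pre-search plus Marquardt polish still reaches the global SSR."""
        traj = cg.integrate_model("logistic", logistic_params, cg.day_grid(150))
        spec = FitSpec(
            "logistic",
            free=("growth_rate", "carrying_capacity"),
            fixed={"initial_biomass": logistic_params.initial_biomass},
            start={"growth_rate": 0.9, "carrying_capacity": 80.0},
            method="pseudo",
            seed=5,
        )
        result = cg.fit_model(spec, traj.t, traj.biomass)
        assert result.estimates["growth_rate"] == pytest.approx(
            logistic_params.growth_rate, rel=1e-2
        )


class TestCompareModels:
    def test_single_result(self, logistic_trajectory):
        r = cg.fit_model(
            FitSpec("logistic"),
            logistic_trajectory.t,
            logistic_trajectory.biomass,
        )
        ranking = cg.compare_models([r])
        assert ranking[0]["rank"] == 1
        assert ranking[0]["delta_aic"] == 0.0

    def test_tie_broken_by_k_then_ssr(self, logistic_trajectory):
        r1 = cg.fit_model(
            FitSpec("logistic"),
            logistic_trajectory.t,
            logistic_trajectory.biomass,
        )
        import copy

        r2 = copy.deepcopy(r1)
        r2.k = r1.k + 2
        r2.aic = r1.aic
        r2.model_id = cg.ModelId.IRRADIANCE
        ranking = cg.compare_models([r2, r1])
        assert ranking[0]["model"] == "logistic"

    def test_mixed_series_rejected(self, logistic_trajectory, water_trajectory):
        r1 = cg.fit_model(
            FitSpec("logistic"),
            logistic_trajectory.t,
            logistic_trajectory.biomass,
        )
        r2 = cg.fit_model(
            FitSpec("logistic"),
            water_trajectory.t,
            water_trajectory.biomass,
        )
        with pytest.raises(ValueError, match="different"):
            cg.compare_models([r1, r2])

    def test_useless_seasonal_amplitude_penalized(self, logistic_trajectory):
        """On noisy logistic data the irradiance model's extra two
        parameters cost more AIC than its amplitude can buy."""
        rng = np.random.default_rng(17)
        y = np.maximum(
            logistic_trajectory.biomass
            + rng.normal(0, 0.005, len(logistic_trajectory.biomass)),
            0.0,
        )
        r_log = cg.fit_model(FitSpec("logistic"), logistic_trajectory.t, y)
        r_irr = cg.fit_model(FitSpec("irradiance"), logistic_trajectory.t, y)
        assert abs(r_irr.estimates["amplitude"]) < 0.01
        assert r_log.aic < r_irr.aic
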