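"""Right-hand sides, the logistic closed form, and the temperature response."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cropgrowth as cg
from cropgrowth.models import effective_irradiance_rate, water_rhs


class TestLogistic:
    def test_zero_biomass_is_fixed_point(self, logistic_params):
        assert cg.logistic_rhs(3.0, 0.0, logistic_params) == 0.0

    def test_carrying_capacity_is_fixed_point(self, logistic_params):
        cap = logistic_params.carrying_capacity
        assert cg.logistic_rhs(0.0, cap, logistic_params) == pytest.approx(0.0)

    def test_half_capacity_rate(self):
        p = cg.LogisticParams(0.2, 1.0, 0.01)
        assert cg.logistic_rhs(0.0, 0.5, p) == pytest.approx(0.05)

    def test_closed_form_initial_condition(self, logistic_params):
        assert cg.logistic_closed_form(0.0, logistic_params) == pytest.approx(
            logistic_params.initial_biomass
        )

    def test_closed_form_zero_rate_is_constant(self):
        p = cg.LogisticParams(0.0, 1.0, 0.3)
        for t in (0.0, 5.0, 400.0):
            assert cg.logistic_closed_form(t, p) == pytest.approx(0.3)

    def test_closed_form_hand_value(self):
        p = cg.LogisticParams(0.5, 1.0, 0.1)
        assert cg.logistic_closed_form(10.0, p) == pytest.approx(
            0.94283, abs=1e-5
        )

    def test_closed_form_strictly_increasing(self, logistic_params):
        t = np.linspace(0, 150, 400)
        m = cg.logistic_closed_form(t, logistic_params)
        assert np.all(np.diff(m) > 0)

    def test_nonfinite_rejected(self, logistic_params):
        with pytest.raises(ValueError):
            cg.logistic_rhs(0.0, np.nan, logistic_params)
        with pytest.raises(ValueError):
            cg.logistic_closed_form(np.inf, logistic_params)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"growth_rate": -0.1, "carrying_capacity": 1, "initial_biomass": 0.1},
            {"growth_rate": 0.1, "carrying_capacity": 0, "initial_biomass": 0.1},
            {"growth_rate": 0.1, "carrying_capacity": 1, "initial_biomass": 0.0},
            {"growth_rate": 0.1, "carrying_capacity": 1, "initial_biomass": 1.5},
        ],
    )
    def test_logistic_invariants(self, kwargs):
        with pytest.raises(ValueError):
            cg.LogisticParams(**kwargs)

    def test_amplitude_above_rate_warns_not_errors(self):
        with pytest.warns(UserWarning):
            p = cg.IrradianceParams(0.05, 1.0, 0.1, amplitude=0.2)
        assert p.amplitude == 0.2

    def test_water_uptake_exponent_range(self, water_params):
        from dataclasses import replace

        with pytest.raises(ValueError):
            replace(water_params, uptake_exponent=0.0)
        with pytest.raises(ValueError):
            replace(water_params, uptake_exponent=1.2)
        with pytest.raises(ValueError):
            replace(water_params, infiltration_fraction=1.5)

    def test_temperature_response_boundary_order(self):
        with pytest.raises(ValueError):
            cg.TemperatureResponseParams(t_low=305.0, t_high=303.0)


class TestIrradiance:
    def test_collapses_to_logistic_bit_identical(self, logistic_params):
        p = cg.IrradianceParams(
            logistic_params.growth_rate,
            logistic_params.carrying_capacity,
            logistic_params.initial_biomass,
            amplitude=0.0,
            phase=17.0,
        )
        for t in np.linspace(0, 365, 50):
            for m in np.linspace(0.0, 1.2, 13):
                assert cg.irradiance_rhs(t, m, p) == cg.logistic_rhs(
                    t, m, logistic_params
                )

    def test_zero_biomass(self):
        with pytest.warns(UserWarning):
            p = cg.IrradianceParams(0.1, 1.0, 0.1, amplitude=0.3)
        assert cg.irradiance_rhs(12.0, 0.0, p) == 0.0

    def test_transient_negative_growth_allowed(self):
        with pytest.warns(UserWarning):
            p = cg.IrradianceParams(0.1, 1.0, 0.1, amplitude=0.3, phase=0.0)
        # sin = -1 at t = 3·365/4
        t = 3 * 365 / 4
        assert effective_irradiance_rate(t, p) == pytest.approx(-0.2)
        assert cg.irradiance_rhs(t, 0.5, p) < 0


class TestTemperatureResponse:
    @pytest.mark.parametrize(
        "kelvin, expected",
        [(292.0, 0.49986), (303.0, 0.48003), (297.5, 0.7648)],
    )
    def test_reference_values(self, kelvin, expected):
        assert cg.temperature_response(kelvin) == pytest.approx(
            expected, abs=5e-5
        )

    def test_matches_direct_formula(self):
        # independent plain-numpy evaluation, no clipping
        T = np.linspace(273.0, 320.0, 97)
        direct = 1.0 / (
            1.0 + np.exp(2e4 / T - 2e4 / 292.0) + np.exp(6e4 / 303.0 - 6e4 / T)
        )
        np.testing.assert_allclose(
            cg.temperature_response(T), direct, atol=1e-12
        )

    def test_unimodal_with_peak_in_tolerance_window(self):
        T = np.linspace(250.0, 330.0, 4001)
        f = cg.temperature_response(T)
        assert np.all(f > 0) and np.all(f < 1)
        peak = T[np.argmax(f)]
        assert 292.0 < peak < 303.0
        i = np.argmax(f)
        assert np.all(np.diff(f[: i + 1]) > 0)
        assert np.all(np.diff(f[i:]) < 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(min_value=1.0, max_value=5000.0))
    def test_bounded_everywhere(self, kelvin):
        f = cg.temperature_response(kelvin)
        assert 0.0 <= f < 1.0

    def test_extreme_cold_saturates_to_zero(self):
        # exponent would overflow without clipping
        assert cg.temperature_response(1e-2 + 1.0) >= 0.0

    def test_rhs_is_product_of_logistic_and_response(self):
        p = cg.TemperatureModelParams(0.2, 1.0, 0.01)
        val = cg.temperature_rhs(5.0, 0.5, p, lambda t: 297.5)
        assert val == pytest.approx(0.05 * 0.764763, rel=1e-5)

    def test_nonpositive_kelvin_rejected(self):
        with pytest.raises(ValueError):
            cg.temperature_response(-3.0)


class TestWaterRHS:
    def test_absorbing_origin(self, water_params):
        dW, dM = water_rhs(0.0, [0.0, 0.0], water_params, lambda t: 0.0)
        assert dW == 0.0 and dM == 0.0

    def test_zero_biomass_keeps_biomass_zero(self, water_params):
        _, dM = water_rhs(0.0, [5.0, 0.0], water_params, lambda t: 10.0)
        assert dM == 0.0

    def test_barren_soil_infiltration_reduces_to_pq(self, water_params):
        # at M = 0 and R·W removed the water equation is p·q·P − uptake(0)
        for P in (0.0, 3.0, 17.5):
            dW, _ = water_rhs(0.0, [0.0, 0.0], water_params, lambda t, P=P: P)
            expected = (
                water_params.precip_conversion
                * water_params.infiltration_fraction
                * P
            )
            assert dW == pytest.approx(expected)

    def test_half_saturation_point(self):
        from dataclasses import replace

        p = replace(
            REFERENCE := cg.WaterModelParams(
                precip_conversion=1.0,
                infiltration_fraction=0.1,
                infiltration_constant=1.0,
                uptake_rate=0.3,
                half_saturation=2.0,
                uptake_exponent=1.0,
                drying_rate=0.0,
                conversion_efficiency=0.8,
                maintenance_rate=0.05,
                initial_soil_water=1.0,
                initial_biomass=0.1,
            )
        )
        # W = n makes the Michaelis-Menten factor exactly 1/2
        _, dM = water_rhs(0.0, [2.0, 1.0], p, lambda t: 0.0)
        assert dM == pytest.approx(0.8 * 0.3 / 2 - 0.05)

    def test_nonfinite_state_rejected(self, water_params):
        with pytest.raises(ValueError):
            water_rhs(0.0, [np.nan, 0.1], water_params, lambda t: 0.0)
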