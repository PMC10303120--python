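"""Right-hand sides of the four growth models, plus analytic helpers.

All RHS functions share one signature contract

    rhs(t, state, params, drivers) -> dstate/dt

with ``state`` a 1-d array (length 1 for the biomass-only models, length 2
``[W, M]`` for the soil-water model) and ``drivers`` a mapping of driver
name ("temperature", "precipitation") to a callable of time.  This keeps
the integration engine model-agnostic.
"""

from __future__ import annotations

import math
from typing import Callable, Mapping

import numpy as np

from .params import (
    IrradianceParams,
    LogisticParams,
    ModelId,
    TemperatureModelParams,
    TemperatureResponseParams,
    WaterModelParams,
)

Drivers = Mapping[str, Callable[[float], float]]

# exp() overflows just above 709; clipping the argument keeps the response
# saturating smoothly toward 0 instead of raising
_EXP_CLIP = 700.0

DAYS_PER_YEAR = 365.0


def _check_finite(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite value for {name}: {v!r}")


def logistic_rhs(t: float, M: float, params: LogisticParams) -> float:
    """Growth rate r·M·(1 − M/M_max) of the logistic model."""
    _check_finite(t=t, M=M)
    return params.growth_rate * M * (1.0 - M / params.carrying_capacity)


def logistic_closed_form(t, params: LogisticParams):
    """Explicit logistic solution M(t) = M_max / (1 + (M_max/M₀ − 1)e^{−rt}).

    Accepts scalar or array ``t``; used as the exact oracle for the
    numerical integrator.
    """
    t = np.asarray(t, dtype=float)
    _check_finite(t=t)
    if params.initial_biomass == 0:
        raise ValueError("closed form undefined for initial_biomass = 0")
    ratio = params.carrying_capacity / params.initial_biomass - 1.0
    out = params.carrying_capacity / (
        1.0 + ratio * np.exp(-params.growth_rate * t)
    )
    return float(out) if out.ndim == 0 else out


def effective_irradiance_rate(t: float, params: IrradianceParams) -> float:
    """Seasonally modulated rate r + A·sin(2π(t + φ)/365)."""
    return params.growth_rate + params.amplitude * math.sin(
        2.0 * math.pi * (t + params.phase) / DAYS_PER_YEAR
    )


def irradiance_rhs(t: float, M: float, params: IrradianceParams) -> float:
    """Logistic growth with the rate modulated by the seasonal sinusoid.

    Collapses exactly to :func:`logistic_rhs` when amplitude is zero.
    """
    _check_finite(t=t, M=M)
    return (
        effective_irradiance_rate(t, params)
        * M
        * (1.0 - M / params.carrying_capacity)
    )


def temperature_response(T, params: TemperatureResponseParams = None):
    """Active-enzyme fraction f(T) ∈ (0, 1) at absolute temperature T (K).

    f(T) = (1 + exp(T_AL/T − T_AL/T_L) + exp(T_AH/T_H − T_AH/T))⁻¹

    Unimodal: both exponentials grow away from the tolerance window
    [T_L, T_H], so the response peaks between the two boundaries and
    decays toward zero outside.  Exponent arguments are clipped so the
    response saturates to ~0 instead of overflowing.
    """
    if params is None:
        params = TemperatureResponseParams()
    T = np.asarray(T, dtype=float)
    _check_finite(T=T)
    if np.any(T <= 0):
        raise ValueError("absolute temperature must be positive")
    a_low = np.clip(
        params.arrhenius_low / T - params.arrhenius_low / params.t_low,
        None,
        _EXP_CLIP,
    )
    a_high = np.clip(
        params.arrhenius_high / params.t_high - params.arrhenius_high / T,
        None,
        _EXP_CLIP,
    )
    out = 1.0 / (1.0 + np.exp(a_low) + np.exp(a_high))
    return float(out) if out.ndim == 0 else out


def temperature_rhs(
    t: float,
    M: float,
    params: TemperatureModelParams,
    temperature: Callable[[float], float],
) -> float:
    """Logistic growth with the rate scaled by f(T(t)).

    ``temperature`` must return the ambient temperature in Kelvin.
    """
    _check_finite(t=t, M=M)
    f_t = temperature_response(temperature(t), params.response)
    return (
        params.growth_rate * f_t * M * (1.0 - M / params.carrying_capacity)
    )


def water_rhs(
    t: float,
    state,
    params: WaterModelParams,
    precipitation: Callable[[float], float],
):
    """Coupled soil-water / biomass derivatives ``[dW/dt, dM/dt]``.

    dW/dt = p·((M + K·q)/(M + K))·P(t) − c·(W/(W+n))·M^v − R·W
    dM/dt = g·c·(W/(W+n))·M^v − m·M

    At M = 0 the infiltration factor reduces to q (barren-soil limit) and
    dM/dt = 0, so the origin is absorbing for biomass.  Transient small
    negative state values from an adaptive solver are tolerated by
    evaluating the nonlinear terms on max(state, 0).
    """
    W, M = float(state[0]), float(state[1])
    _check_finite(t=t, W=W, M=M)
    p = params
    if W + p.half_saturation == 0:
        raise ValueError("uptake term undefined: soil water + half_saturation = 0")
    Wp, Mp = max(W, 0.0), max(M, 0.0)
    K = p.infiltration_constant
    if K == 0.0:
        infil = 1.0 if Mp > 0 else p.infiltration_fraction
    else:
        infil = (Mp + K * p.infiltration_fraction) / (Mp + K)
    uptake = (
        p.uptake_rate
        * (Wp / (Wp + p.half_saturation))
        * Mp**p.uptake_exponent
    )
    dW = p.precip_conversion * infil * precipitation(t) - uptake - p.drying_rate * W
    dM = p.conversion_efficiency * uptake - p.maintenance_rate * M
    return np.array([dW, dM])


def rhs_for(model_id: ModelId):
    """Uniform ``(t, state_vector, params, drivers) -> derivative_vector`` view.

    Adapts every model to the shared signature used by the integrator;
    the biomass-only models use a length-1 state vector.
    """
    model_id = ModelId(model_id)

    if model_id is ModelId.LOGISTIC:

        def rhs(t, state, params, drivers: Drivers):
            return np.array([logistic_rhs(t, state[0], params)])

    elif model_id is ModelId.IRRADIANCE:

        def rhs(t, state, params, drivers: Drivers):
            return np.array([irradiance_rhs(t, state[0], params)])

    elif model_id is ModelId.TEMPERATURE:

        def rhs(t, state, params, drivers: Drivers):
            return np.array(
                [temperature_rhs(t, state[0], params, drivers["temperature"])]
            )

    else:

        def rhs(t, state, params, drivers: Drivers):
            return water_rhs(t, state, params, drivers["precipitation"])

    return rhs


def initial_state(model_id: ModelId, params) -> np.ndarray:
    """Initial state vector for a model ([M₀] or [W₀, M₀])."""
    if ModelId(model_id) is ModelId.WATER:
        return np.array([params.initial_soil_water, params.initial_biomass])
    return np.array([params.initial_biomass])


def required_drivers(model_id: ModelId) -> tuple[str, ...]:
    """Driver names a model needs at integration time."""
    return {
        ModelId.LOGISTIC: (),
        ModelId.IRRADIANCE: (),
        ModelId.TEMPERATURE: ("temperature",),
        ModelId.WATER: ("precipitation",),
    }[ModelId(model_id)]
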