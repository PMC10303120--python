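"""Numerical integration of the growth models over a time grid."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .models import initial_state, required_drivers, rhs_for
from .params import ModelId, WaterModelParams


@dataclass(frozen=True)
class SolverSettings:
    """Adaptive-solver configuration.

    Defaults (explicit Runge–Kutta 4/5, rtol 1e-8, atol 1e-10) resolve the
    biomass-only models far below observation noise; ``stiff_fallback``
    retries with an implicit method when the explicit solver's step size
    collapses, which can happen for the soil-water model under fast
    drying.
    """

    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = np.inf
    method: str = "RK45"
    stiff_method: str = "LSODA"
    stiff_fallback: bool = True

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("solver tolerances must be positive")


class SolverError(RuntimeError):
    """Raised when integration fails; carries the failing time."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


@dataclass
class Trajectory:
    """A realized model solution on a day grid.

    ``biomass`` (and ``soil_water`` for the water model) are floored at 0
    for reporting — the dynamics keep M = 0 and W = 0 as natural
    boundaries, but an adaptive solver may undershoot by roundoff.
    """

    t: np.ndarray
    biomass: np.ndarray
    model_id: ModelId
    params: object
    soil_water: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.biomass = np.maximum(np.asarray(self.biomass, dtype=float), 0.0)
        if self.soil_water is not None:
            self.soil_water = np.maximum(
                np.asarray(self.soil_water, dtype=float), 0.0
            )
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if len(self.biomass) != len(self.t):
            raise ValueError("biomass length does not match time grid")
        if self.soil_water is not None and len(self.soil_water) != len(self.t):
            raise ValueError("soil_water length does not match time grid")

    def __len__(self) -> int:
        return len(self.t)


def day_grid(n_days: int, start: float = 0.0) -> np.ndarray:
    """Integer-day output grid [start, start+1, ..., start+n_days]."""
    return start + np.arange(n_days + 1, dtype=float)


def integrate_model(
    model_id: ModelId,
    params,
    t_grid,
    drivers: dict | None = None,
    settings: SolverSettings | None = None,
) -> Trajectory:
    """Integrate a model over ``t_grid`` and return its :class:`Trajectory`.

    Parameters
    ----------
    model_id : ModelId
        Which model to integrate.
    params
        The matching parameter record (supplies the initial state).
    t_grid : array-like
        Strictly increasing output times (days); integration spans
        [t_grid[0], t_grid[-1]].
    drivers : dict, optional
        Smoothed drivers keyed by name; the temperature model requires
        "temperature" (Kelvin), the water model "precipitation".  Each
        driver's domain must cover the grid.
    settings : SolverSettings, optional

    Raises
    ------
    SolverError
        If both the explicit solver and the stiff fallback fail; the
        exception carries the failing time.
    """
    model_id = ModelId(model_id)
    drivers = drivers or {}
    settings = settings or SolverSettings()
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    for name in required_drivers(model_id):
        if name not in drivers:
            raise ValueError(f"model '{model_id.value}' requires a '{name}' driver")
        lo, hi = drivers[name].domain
        if t_grid[0] < lo or t_grid[-1] > hi:
            raise ValueError(
                f"t_grid [{t_grid[0]}, {t_grid[-1]}] outside the domain "
                f"[{lo}, {hi}] of driver '{name}'"
            )

    rhs = rhs_for(model_id)
    y0 = initial_state(model_id, params)

    def fun(t, y):
        return rhs(t, y, params, drivers)

    methods = [settings.method]
    if settings.stiff_fallback and settings.stiff_method != settings.method:
        methods.append(settings.stiff_method)
    sol = None
    for method in methods:
        sol = solve_ivp(
            fun,
            (t_grid[0], t_grid[-1]),
            y0,
            method=method,
            t_eval=t_grid,
            rtol=settings.rtol,
            atol=settings.atol,
            max_step=settings.max_step,
        )
        if sol.success:
            break
    if sol is None or not sol.success:
        t_fail = float(sol.t[-1]) if sol is not None and len(sol.t) else None
        raise SolverError(
            f"integration of '{model_id.value}' failed"
            + (f" at t={t_fail:.3f}" if t_fail is not None else "")
            + f": {sol.message if sol is not None else 'no solution'}",
            t_fail=t_fail,
        )

    if model_id is ModelId.WATER:
        return Trajectory(
            t=t_grid,
            biomass=sol.y[1],
            soil_water=sol.y[0],
            model_id=model_id,
            params=params,
        )
    return Trajectory(t=t_grid, biomass=sol.y[0], model_id=model_id, params=params)


def steady_state_soil_water(params: WaterModelParams, p_const: float) -> float:
    """Equilibrium soil water p·q·P/R under constant precipitation and M = 0.

    With no crop, infiltration is p·q·P and loss R·W; setting dW/dt = 0
    gives the balance point the bucket relaxes to (0 when it never rains).
    """
    if params.drying_rate == 0:
        raise ValueError("no steady state when drying_rate is 0")
    if p_const < 0:
        raise ValueError("precipitation must be non-negative")
    return (
        params.precip_conversion
        * params.infiltration_fraction
        * p_const
        / params.drying_rate
    )
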