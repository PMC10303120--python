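"""Continuous environmental drivers from daily weather observations.

The temperature and soil-water models need weather as smooth functions of
time, not daily step functions: an adaptive ODE solver queries the driver
at arbitrary (non-integer) times, and a differentiable input keeps the
fitted trajectories smooth.  Daily series are therefore smoothed with a
cubic penalized spline whose penalty is chosen by generalized
cross-validation unless given explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.interpolate import make_smoothing_spline

ABSOLUTE_ZERO_C = -273.15

#: longest run of missing days the spline may interpolate across; wider
#: gaps would fabricate weather and raise instead
MAX_GAP_DAYS = 10

#: drivers stay valid this many days beyond the data range at each end, so
#: a small solver overshoot past the last observation does not abort a run
DOMAIN_PAD_DAYS = 1.0


def celsius_to_kelvin(t_celsius):
    """Convert °C to K, rejecting values below absolute zero."""
    t = np.asarray(t_celsius, dtype=float)
    if np.any(t <= ABSOLUTE_ZERO_C):
        raise ValueError(f"temperature below absolute zero: {t_celsius!r}")
    out = t + 273.15
    return float(out) if out.ndim == 0 else out


@dataclass
class EnvironmentSeries:
    """Daily weather observations for one trial.

    Temperatures in °C, precipitation in mm day⁻¹ (numerically equal to
    ml m⁻² day⁻¹).  Days are an integer-valued, strictly increasing index;
    gaps are allowed and handled at smoothing time.
    """

    day: np.ndarray
    t_avg: np.ndarray
    precipitation: np.ndarray
    t_min: np.ndarray | None = None
    t_max: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.day = np.asarray(self.day, dtype=float)
        self.t_avg = np.asarray(self.t_avg, dtype=float)
        self.precipitation = np.asarray(self.precipitation, dtype=float)
        if self.t_min is not None:
            self.t_min = np.asarray(self.t_min, dtype=float)
        if self.t_max is not None:
            self.t_max = np.asarray(self.t_max, dtype=float)
        n = len(self.day)
        for name in ("t_avg", "precipitation", "t_min", "t_max"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
        if np.any(np.diff(self.day) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(self.precipitation < 0):
            raise ValueError("negative precipitation")
        if self.t_min is not None and np.any(self.t_min > self.t_avg):
            raise ValueError("t_min exceeds t_avg")
        if self.t_max is not None and np.any(self.t_max < self.t_avg):
            raise ValueError("t_max below t_avg")

    def __len__(self) -> int:
        return len(self.day)


@dataclass
class SmoothedDriver:
    """A continuous, deterministic function of time on a closed domain."""

    domain: tuple[float, float]
    evaluator: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    smoothing_penalty: float | None = None
    clip_min: float | None = None
    name: str = "driver"

    def __call__(self, t):
        t_arr = np.asarray(t, dtype=float)
        lo, hi = self.domain
        if np.any(t_arr < lo) or np.any(t_arr > hi):
            raise ValueError(
                f"driver '{self.name}' evaluated at t={t!r}, outside "
                f"domain [{lo}, {hi}]"
            )
        out = np.asarray(self.evaluator(t_arr), dtype=float)
        if self.clip_min is not None:
            out = np.maximum(out, self.clip_min)
        return float(out) if out.ndim == 0 else out


def evaluate_driver(driver: SmoothedDriver, t):
    """Functional alias for ``driver(t)``."""
    return driver(t)


def smooth_daily_series(
    days,
    values,
    penalty: float | str = "auto",
    clip_min: float | None = None,
    name: str = "driver",
) -> SmoothedDriver:
    """Fit a cubic penalized spline to a daily series.

    Parameters
    ----------
    days, values : array-like
        Strictly increasing day indices and the observed values; at least
        4 points.  Gaps wider than ``MAX_GAP_DAYS`` raise.
    penalty : float or "auto"
        Roughness penalty λ; "auto" selects λ by generalized
        cross-validation.  λ = 0 interpolates, λ → ∞ tends to the
        least-squares line (the penalty null space).
    clip_min : float, optional
        Floor applied at evaluation time (e.g. 0 for rainfall, where the
        smoother may undershoot near sharp peaks).
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(days) < 4:
        raise ValueError(f"need at least 4 data points, got {len(days)}")
    if len(values) != len(days):
        raise ValueError("days and values have different lengths")
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    if not np.all(np.isfinite(days)) or not np.all(np.isfinite(values)):
        raise ValueError("non-finite values in the series")
    gaps = np.diff(days)
    if np.any(gaps > MAX_GAP_DAYS):
        i = int(np.argmax(gaps))
        raise ValueError(
            f"gap of {gaps[i]:.0f} days after day {days[i]:.0f} exceeds the "
            f"{MAX_GAP_DAYS}-day interpolation limit"
        )
    lam = None if penalty in ("auto", None) else float(penalty)
    spline = make_smoothing_spline(days, values, lam=lam)
    domain = (days[0] - DOMAIN_PAD_DAYS, days[-1] + DOMAIN_PAD_DAYS)
    return SmoothedDriver(
        domain=domain,
        evaluator=spline,
        smoothing_penalty=lam,
        clip_min=clip_min,
        name=name,
    )


def temperature_driver(
    series: EnvironmentSeries,
    which: str = "t_avg",
    penalty: float | str = "auto",
) -> SmoothedDriver:
    """Smoothed absolute-temperature driver (Kelvin) from daily °C data.

    ``which`` selects the smoothed series: "t_avg" (default), "t_min" or
    "t_max".
    """
    if which not in ("t_avg", "t_min", "t_max"):
        raise ValueError(f"unknown temperature series {which!r}")
    values = getattr(series, which)
    if values is None:
        raise ValueError(f"series has no {which} data")
    return smooth_daily_series(
        series.day,
        celsius_to_kelvin(values),
        penalty=penalty,
        name=f"temperature[{which}]",
    )


def precipitation_driver(
    series: EnvironmentSeries, penalty: float | str = "auto"
) -> SmoothedDriver:
    """Smoothed precipitation driver, clipped at zero (rain cannot be negative)."""
    return smooth_daily_series(
        series.day,
        series.precipitation,
        penalty=penalty,
        clip_min=0.0,
        name="precipitation",
    )


def constant_driver(value: float, t_start: float, t_end: float, name="constant"):
    """Driver that is identically ``value`` on [t_start, t_end]; handy for
    steady-state analysis and tests."""
    return SmoothedDriver(
        domain=(t_start, t_end),
        evaluator=lambda t: np.full_like(np.asarray(t, dtype=float), float(value)),
        smoothing_penalty=None,
        name=name,
    )
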