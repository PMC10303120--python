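"""Least-squares estimation of growth-model parameters from one series.

A model is fitted to a single genotype-by-trial series by minimizing the
sum of squared residuals between the numerically integrated trajectory
and the observations.  Any subset of parameters and initial conditions
can be freed; the rest are held fixed.  Three optimizers are provided —
Levenberg–Marquardt ("marq", the default), Nelder–Mead, and a seeded
Latin-hypercube pre-search ("pseudo") polished by Levenberg–Marquardt —
optionally combined with multistart for the multi-optimum soil-water
model.  Fit quality is summarized by SSR, AIC (Gaussian concentrated
form) and the residual series.

Free parameters are optimized on transformed scales that build the sign
and range constraints into the search space: positive quantities on a
log scale, fractions in (0, 1] on a logit scale, and the seasonal
amplitude/phase on a linear scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .drivers import SmoothedDriver
from .params import (
    PARAM_CLASSES,
    ModelId,
    TemperatureResponseParams,
)
from .simulate import SolverError, SolverSettings, Trajectory, integrate_model

#: biomass is divided by this before fitting, mirroring common practice of
#: bringing the objective to order one for better optimizer conditioning
BIOMASS_RESCALE = 1000.0

#: residual value substituted when the ODE solver fails or parameters are
#: momentarily invalid during a search step
_PENALTY_RESIDUAL = 1e6

#: infinity-norm gradient threshold for the convergence flag
_GRAD_TOL = 1e-2

_LOG, _LOGIT, _LINEAR = "log", "logit", "linear"

#: fittable quantities per model: name -> transform used during optimization
PARAM_TRANSFORMS: dict[ModelId, dict[str, str]] = {
    ModelId.LOGISTIC: {
        "growth_rate": _LOG,
        "carrying_capacity": _LOG,
        "initial_biomass": _LOG,
    },
    ModelId.IRRADIANCE: {
        "growth_rate": _LOG,
        "carrying_capacity": _LOG,
        "initial_biomass": _LOG,
        "amplitude": _LINEAR,
        "phase": _LINEAR,
    },
    ModelId.TEMPERATURE: {
        "growth_rate": _LOG,
        "carrying_capacity": _LOG,
        "initial_biomass": _LOG,
    },
    ModelId.WATER: {
        "precip_conversion": _LOG,
        "infiltration_fraction": _LOGIT,
        "infiltration_constant": _LOG,
        "uptake_rate": _LOG,
        "half_saturation": _LOG,
        "uptake_exponent": _LOGIT,
        "drying_rate": _LOG,
        "conversion_efficiency": _LOG,
        "maintenance_rate": _LOG,
        "initial_soil_water": _LOG,
        "initial_biomass": _LOG,
    },
}

INITIAL_CONDITION_NAMES: dict[ModelId, tuple[str, ...]] = {
    ModelId.LOGISTIC: ("initial_biomass",),
    ModelId.IRRADIANCE: ("initial_biomass",),
    ModelId.TEMPERATURE: ("initial_biomass",),
    ModelId.WATER: ("initial_soil_water", "initial_biomass"),
}

#: default search bounds in user units, used by the pseudo pre-search and
#: multistart draws (data-dependent entries are resolved at fit time)
_DEFAULT_BOUNDS: dict[ModelId, dict[str, tuple[float, float]]] = {
    ModelId.LOGISTIC: {
        "growth_rate": (1e-3, 1.0),
        "carrying_capacity": (1e-3, 1e2),
        "initial_biomass": (1e-6, 1.0),
    },
    ModelId.IRRADIANCE: {
        "growth_rate": (1e-3, 1.0),
        "carrying_capacity": (1e-3, 1e2),
        "initial_biomass": (1e-6, 1.0),
        "amplitude": (-0.5, 0.5),
        "phase": (-182.5, 182.5),
    },
    ModelId.TEMPERATURE: {
        "growth_rate": (1e-3, 2.0),
        "carrying_capacity": (1e-3, 1e2),
        "initial_biomass": (1e-6, 1.0),
    },
    ModelId.WATER: {
        "precip_conversion": (1e-2, 1e2),
        "infiltration_fraction": (1e-4, 1.0),
        "infiltration_constant": (1e-2, 1e4),
        "uptake_rate": (1e-4, 1e1),
        "half_saturation": (1e-3, 1e3),
        "uptake_exponent": (1e-2, 1.0),
        "drying_rate": (1e-5, 1.0),
        "conversion_efficiency": (1e-3, 1e2),
        "maintenance_rate": (1e-5, 1.0),
        "initial_soil_water": (1e-3, 1e2),
        "initial_biomass": (1e-6, 1.0),
    },
}

METHODS = ("marq", "nelder-mead", "pseudo")


def fittable_parameters(model_id: ModelId) -> tuple[str, ...]:
    """Names of all parameters and initial conditions a model exposes to
    the fitting procedure (temperature-response constants are excluded:
    they are held fixed, with no genotypic variation)."""
    return tuple(PARAM_TRANSFORMS[ModelId(model_id)])


# ---------------------------------------------------------------------------
# transforms

def _to_internal(x: float, kind: str) -> float:
    if kind == _LOG:
        return float(np.log(np.clip(x, 1e-300, None)))
    if kind == _LOGIT:
        x = float(np.clip(x, 1e-12, 1.0 - 1e-12))
        return float(np.log(x / (1.0 - x)))
    return float(x)


def _from_internal(theta: float, kind: str) -> float:
    if kind == _LOG:
        return float(np.exp(np.clip(theta, -700.0, 700.0)))
    if kind == _LOGIT:
        return float(1.0 / (1.0 + np.exp(-np.clip(theta, -700.0, 700.0))))
    return float(theta)


# ---------------------------------------------------------------------------
# specification and result containers

@dataclass
class FitSpec:
    """Which model to fit, which quantities are free, and how.

    Attributes
    ----------
    model_id : ModelId
    free : tuple of str
        Names of the quantities to estimate; defaults to every fittable
        quantity of the model.
    fixed : dict
        Values for the remaining quantities.  ``free`` and ``fixed``
        together must cover the model's fittable set exactly once.
    bounds : dict
        Per-quantity (low, high) search bounds in user units; merged over
        the defaults.  Used by the pseudo search and multistart draws.
    method : str
        "marq" (Levenberg–Marquardt, default), "nelder-mead", or
        "pseudo" (Latin-hypercube pre-search + Marquardt polish).
    multistart : int
        Number of optimizer starts; starts beyond the first are seeded
        Latin-hypercube draws within the bounds.
    seed : int
        Seed for the pseudo search and multistart draws.
    start : dict
        Optional explicit initial guesses (user units) overriding the
        data-driven defaults.
    biomass_rescale : bool
        Divide biomass by 1000 inside the objective (default on).
    soil_water_weight : str or float
        Weight of the soil-water residual block in the joint water-model
        objective: "auto" scales each state's residuals by the reciprocal
        standard deviation of its observed series; a float is used as a
        fixed multiplier on the soil-water residuals.
    response : TemperatureResponseParams
        Fixed temperature-response constants (temperature model only).
    """

    model_id: ModelId
    free: tuple[str, ...] | None = None
    fixed: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    method: str = "marq"
    multistart: int = 1
    seed: int = 0
    start: dict[str, float] = field(default_factory=dict)
    biomass_rescale: bool = True
    soil_water_weight: str | float = "auto"
    response: TemperatureResponseParams = field(
        default_factory=TemperatureResponseParams
    )

    def __post_init__(self) -> None:
        self.model_id = ModelId(self.model_id)
        all_names = fittable_parameters(self.model_id)
        if self.free is None:
            self.free = tuple(n for n in all_names if n not in self.fixed)
        self.free = tuple(self.free)
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.multistart < 1:
            raise ValueError("multistart must be >= 1")
        overlap = set(self.free) & set(self.fixed)
        if overlap:
            raise ValueError(f"quantities both free and fixed: {sorted(overlap)}")
        unknown = (set(self.free) | set(self.fixed) | set(self.bounds)) - set(
            all_names
        )
        if unknown:
            raise ValueError(
                f"unknown quantities for model '{self.model_id.value}': "
                f"{sorted(unknown)}"
            )
        missing = set(all_names) - set(self.free) - set(self.fixed)
        if missing:
            raise ValueError(
                f"quantities neither free nor fixed: {sorted(missing)}"
            )
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"empty bound for {name}: ({lo}, {hi})")

    @property
    def k(self) -> int:
        """Number of estimated quantities (#θ in the AIC penalty)."""
        return len(self.free)

    def resolved_bounds(self) -> dict[str, tuple[float, float]]:
        out = dict(_DEFAULT_BOUNDS[self.model_id])
        out.update(self.bounds)
        return {n: out[n] for n in self.free}


@dataclass
class ResidualSeries:
    """Residuals r_i = f(x_i) − y_i (model minus observation) on the
    observation grid, with optional per-point weights (default 1)."""

    t: np.ndarray
    residuals: np.ndarray
    state: str = "biomass"
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.residuals = np.asarray(self.residuals, dtype=float)
        if len(self.t) != len(self.residuals):
            raise ValueError("residual length does not match grid")
        if self.weights is None:
            self.weights = np.ones_like(self.residuals)


@dataclass
class FitResult:
    """Outcome of one model fit to one series."""

    model_id: ModelId
    estimates: dict[str, float]
    fixed: dict[str, float]
    ssr: float
    n_obs: int
    k: int
    aic: float
    residuals: dict[str, ResidualSeries]
    converged: bool
    method: str
    objective: float
    multistart_trace: list[float]
    params: object
    t_obs: np.ndarray
    biomass_obs: np.ndarray

    def summary(self) -> str:
        lines = [
            f"model      : {self.model_id.value}",
            f"method     : {self.method}",
            f"converged  : {self.converged}",
            f"n_obs      : {self.n_obs}",
            f"k (free)   : {self.k}",
            f"SSR        : {self.ssr:.6g}",
            f"AIC        : {self.aic:.4f}",
        ]
        for name, value in self.estimates.items():
            lines.append(f"  {name} = {value:.6g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# elementary operations

def compute_residuals(predicted, observed, t=None, state="biomass", weights=None):
    """Residual series r_i = predicted_i − observed_i (model minus data)."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError(
            f"grid mismatch: predicted has shape {predicted.shape}, "
            f"observed {observed.shape}"
        )
    if t is None:
        t = np.arange(len(predicted), dtype=float)
    return ResidualSeries(
        t=t, residuals=predicted - observed, state=state, weights=weights
    )


def aic(ssr: float, n_obs: int, k: int, literal: bool = False) -> float:
    """Akaike information criterion for a least-squares fit.

    Default is the Gaussian concentrated form ``n·ln(SSR/n) + 2k`` (the
    residual variance profiled out of −2LL, additive constants dropped).
    ``literal=True`` returns the heuristic ``SSR + 2k`` variant in which
    the sum of squared errors itself stands in for −2LL; useful only for
    comparing fits of identical models to identical data under the same
    convention.
    """
    if n_obs <= k:
        raise ValueError(f"need n_obs > k, got n_obs={n_obs}, k={k}")
    if ssr < 0:
        raise ValueError("SSR must be non-negative")
    if ssr == 0:
        warnings.warn("SSR is exactly 0; AIC diverges to -inf", stacklevel=2)
        return -np.inf
    if literal:
        return float(ssr + 2 * k)
    return float(n_obs * np.log(ssr / n_obs) + 2 * k)


def normalize_biomass(values):
    """Rescale biomass by division by 1000 (objective conditioning)."""
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("biomass must be non-negative")
    return values / BIOMASS_RESCALE


# ---------------------------------------------------------------------------
# objective machinery

def _build_params(spec: FitSpec, values: dict[str, float]):
    cls = PARAM_CLASSES[spec.model_id]
    if spec.model_id is ModelId.TEMPERATURE:
        return cls(response=spec.response, **values)
    return cls(**values)


def _default_start(
    spec: FitSpec, t, biomass
) -> dict[str, float]:
    """Data-driven initial guesses for every free quantity."""
    t = np.asarray(t, dtype=float)
    biomass = np.asarray(biomass, dtype=float)
    m_floor = max(1e-6, 1e-3 * float(np.max(biomass)))
    first = max(float(biomass[0]), m_floor)
    peak = float(np.max(biomass))
    # early-season slope of log M approximates the intrinsic rate
    i_q = max(2, len(t) // 4)
    logm = np.log(np.clip(biomass[: i_q + 1], m_floor, None))
    with np.errstate(invalid="ignore"):
        slope = (logm[-1] - logm[0]) / (t[i_q] - t[0])
    r0 = float(np.clip(slope, 1e-3, 1.0))
    guesses = {
        "growth_rate": r0,
        "carrying_capacity": 1.05 * peak,
        "initial_biomass": first,
        "amplitude": 0.01,
        "phase": 0.0,
        # soil-water defaults centered on magnitudes typical of fitted
        # wheat trials (order 1 conversion factors, weakly leaky bucket)
        "precip_conversion": 1.0,
        "infiltration_fraction": 0.05,
        "infiltration_constant": 300.0,
        "uptake_rate": 0.08,
        "half_saturation": 1.0,
        "uptake_exponent": 0.5,
        "drying_rate": 5e-3,
        "conversion_efficiency": 1.0,
        "maintenance_rate": 0.01,
        "initial_soil_water": 2.0,
    }
    out = {n: guesses[n] for n in spec.free}
    out.update({n: v for n, v in spec.start.items() if n in spec.free})
    return out


class _Objective:
    """Residual vector (and SSR) as a function of the transformed free
    parameters, for one model/observation pairing."""

    def __init__(
        self,
        spec: FitSpec,
        t_obs,
        biomass_obs,
        soil_water_obs,
        drivers,
        settings: SolverSettings,
    ):
        self.spec = spec
        self.t = np.asarray(t_obs, dtype=float)
        self.biomass = np.asarray(biomass_obs, dtype=float)
        self.soil_water = (
            None if soil_water_obs is None else np.asarray(soil_water_obs, float)
        )
        self.drivers = drivers or {}
        self.settings = settings
        self.transforms = [PARAM_TRANSFORMS[spec.model_id][n] for n in spec.free]
        scale = BIOMASS_RESCALE if spec.biomass_rescale else 1.0
        self.biomass_scaled = self.biomass / scale
        self.scale = scale
        # per-state weights for the joint objective
        if self.soil_water is not None and spec.model_id is ModelId.WATER:
            if spec.soil_water_weight == "auto":
                sd_m = float(np.std(self.biomass_scaled))
                sd_w = float(np.std(self.soil_water))
                self.w_biomass = 1.0 / sd_m if sd_m > 0 else 1.0
                self.w_water = 1.0 / sd_w if sd_w > 0 else 1.0
            else:
                self.w_biomass = 1.0
                self.w_water = float(spec.soil_water_weight)
        else:
            self.w_biomass = 1.0
            self.w_water = 0.0

    def theta_from_values(self, values: dict[str, float]) -> np.ndarray:
        return np.array(
            [
                _to_internal(values[n], k)
                for n, k in zip(self.spec.free, self.transforms)
            ]
        )

    def values_from_theta(self, theta) -> dict[str, float]:
        return {
            n: _from_internal(th, k)
            for n, th, k in zip(self.spec.free, theta, self.transforms)
        }

    def params_from_theta(self, theta):
        values = dict(self.spec.fixed)
        values.update(self.values_from_theta(theta))
        return _build_params(self.spec, values)

    def predict(self, params) -> Trajectory:
        return integrate_model(
            self.spec.model_id,
            params,
            self.t,
            drivers=self.drivers,
            settings=self.settings,
        )

    def residual_vector(self, theta) -> np.ndarray:
        try:
            params = self.params_from_theta(theta)
            traj = self.predict(params)
        except (ValueError, SolverError):
            n = len(self.t) + (0 if self.soil_water is None else len(self.t))
            return np.full(n, _PENALTY_RESIDUAL)
        res = (traj.biomass / self.scale - self.biomass_scaled) * self.w_biomass
        if self.soil_water is not None and traj.soil_water is not None:
            res_w = (traj.soil_water - self.soil_water) * self.w_water
            res = np.concatenate([res, res_w])
        return res

    def ssr_value(self, theta) -> float:
        r = self.residual_vector(theta)
        return float(r @ r)


def pseudo_search(objective, bounds, n_candidates: int, seed: int):
    """Latin-hypercube pre-search over finite transformed bounds.

    Draws ``n_candidates`` vectors, evaluates ``objective`` (a scalar SSR
    function of the transformed parameter vector) at each, and returns
    ``(best_theta, trace)`` with the evaluated SSRs.  Deterministic under
    a fixed seed.  Intended for crude-but-fast localization, polished
    afterwards by a gradient method.
    """
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ValueError("pseudo search requires finite bounds on all free "
                         "quantities")
    if n_candidates < 1:
        raise ValueError("need at least one candidate")
    sampler = qmc.LatinHypercube(d=len(bounds), seed=seed)
    unit = sampler.random(n_candidates)
    thetas = lo + unit * (hi - lo)
    ssrs = np.array([objective(th) for th in thetas])
    best = int(np.argmin(ssrs))
    return thetas[best], ssrs.tolist()


def _grad_norm(ssr_fn, theta, h=1e-6) -> float:
    g = np.zeros(len(theta))
    f0 = ssr_fn(theta)
    for i in range(len(theta)):
        step = h * max(1.0, abs(theta[i]))
        tp = theta.copy()
        tp[i] += step
        g[i] = (ssr_fn(tp) - f0) / step
    return float(np.max(np.abs(g))) if len(g) else 0.0


def _polish(obj: _Objective, theta0: np.ndarray, method: str):
    """Run one local optimization from theta0; returns (theta, ssr, ok)."""
    if method == "nelder-mead":
        res = optimize.minimize(
            obj.ssr_value,
            theta0,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000},
        )
        grad_ok = _grad_norm(obj.ssr_value, res.x) <= _GRAD_TOL
        return res.x, float(res.fun), bool(res.success) and grad_ok
    # Levenberg-Marquardt on the residual vector with a forward-difference
    # Jacobian; the relative step must stay well above the ODE solver's
    # relative tolerance or integration noise corrupts the derivatives
    res = optimize.least_squares(
        obj.residual_vector,
        theta0,
        method="lm",
        jac="2-point",
        diff_step=1e-4,
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=300 * (len(theta0) + 1),
    )
    ssr = 2.0 * float(res.cost)
    grad_ok = float(np.max(np.abs(res.grad), initial=0.0)) <= _GRAD_TOL * max(
        1.0, ssr
    )
    return res.x, ssr, bool(res.success) and grad_ok


def fit_model(
    spec: FitSpec,
    t_obs,
    biomass_obs,
    soil_water_obs=None,
    drivers: dict[str, SmoothedDriver] | None = None,
    settings: SolverSettings | None = None,
) -> FitResult:
    """Fit one model to one observed series.

    Parameters
    ----------
    spec : FitSpec
        Model, free/fixed split, optimizer and multistart configuration.
    t_obs, biomass_obs : array-like
        Observation days (strictly increasing) and biomass (kg m⁻²).
    soil_water_obs : array-like, optional
        Soil-water observations on the same grid; when given (water model
        only) the objective is the weighted sum of both states' SSRs.
    drivers : dict, optional
        Smoothed drivers required by the model.
    settings : SolverSettings, optional

    Returns
    -------
    FitResult
        Best result over all starts.  ``converged`` is False when no
        start satisfied both the optimizer's own success test and the
        gradient-norm test — never an exception.
    """
    t_obs = np.asarray(t_obs, dtype=float)
    biomass_obs = np.asarray(biomass_obs, dtype=float)
    if np.any(np.diff(t_obs) <= 0):
        raise ValueError("observation days must be strictly increasing")
    if len(t_obs) != len(biomass_obs):
        raise ValueError("t_obs and biomass_obs lengths differ")
    n_obs = len(t_obs)
    if spec.k >= n_obs:
        raise ValueError(
            f"unidentifiable fit: {spec.k} free quantities but only "
            f"{n_obs} observations"
        )
    if soil_water_obs is not None and spec.model_id is not ModelId.WATER:
        raise ValueError("soil-water observations apply to the water model only")

    settings = settings or SolverSettings()
    obj = _Objective(spec, t_obs, biomass_obs, soil_water_obs, drivers, settings)

    start_values = _default_start(spec, t_obs, biomass_obs)
    theta0 = obj.theta_from_values(start_values)
    bounds_user = spec.resolved_bounds()
    theta_bounds = [
        tuple(
            sorted(
                (
                    _to_internal(bounds_user[n][0], k),
                    _to_internal(bounds_user[n][1], k),
                )
            )
        )
        for n, k in zip(spec.free, obj.transforms)
    ]

    starts = [theta0]
    if spec.method == "pseudo":
        theta_ps, _ = pseudo_search(
            obj.ssr_value, theta_bounds, n_candidates=64, seed=spec.seed
        )
        starts = [theta_ps]
    if spec.multistart > 1:
        lo = np.array([b[0] for b in theta_bounds])
        hi = np.array([b[1] for b in theta_bounds])
        sampler = qmc.LatinHypercube(d=len(theta_bounds), seed=spec.seed)
        extra = lo + sampler.random(spec.multistart - 1) * (hi - lo)
        starts.extend(list(extra))

    polish_method = "nelder-mead" if spec.method == "nelder-mead" else "marq"
    best = None
    trace: list[float] = []
    for th0 in starts:
        theta, ssr_obj, ok = _polish(obj, np.asarray(th0, float), polish_method)
        trace.append(ssr_obj)
        if best is None or ssr_obj < best[1]:
            best = (theta, ssr_obj, ok)
    theta_hat, objective_value, converged = best

    params_hat = obj.params_from_theta(theta_hat)
    traj = obj.predict(params_hat)
    scale = obj.scale
    res_biomass = compute_residuals(
        traj.biomass, biomass_obs, t=t_obs, state="biomass"
    )
    residuals = {"biomass": res_biomass}
    # SSR/AIC on the biomass residuals at the fitting scale, so that AIC is
    # comparable across models fitted to the same biomass series
    ssr = float(np.sum((res_biomass.residuals / scale) ** 2))
    if soil_water_obs is not None and traj.soil_water is not None:
        residuals["soil_water"] = compute_residuals(
            traj.soil_water, soil_water_obs, t=t_obs, state="soil_water"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aic_value = aic(ssr, n_obs, spec.k)
    estimates = obj.values_from_theta(theta_hat)

    return FitResult(
        model_id=spec.model_id,
        estimates=estimates,
        fixed=dict(spec.fixed),
        ssr=ssr,
        n_obs=n_obs,
        k=spec.k,
        aic=aic_value,
        residuals=residuals,
        converged=converged,
        method=spec.method,
        objective=objective_value,
        multistart_trace=trace,
        params=params_hat,
        t_obs=t_obs,
        biomass_obs=biomass_obs,
    )


def compare_models(results: list[FitResult]):
    """Rank fits of candidate models to one series by AIC.

    Returns a list of dicts (rank, model, aic, delta_aic, k, ssr,
    converged), AIC ascending; ties broken by smaller k, then lower SSR.
    The ranking is a heuristic reading of AIC — the models are not nested
    (except that the irradiance model contains the logistic one), so
    differences gauge which crude growth pattern matches, not formal
    evidence.
    """
    if not results:
        raise ValueError("no results to compare")
    ref_t, ref_y = results[0].t_obs, results[0].biomass_obs
    for r in results[1:]:
        if len(r.t_obs) != len(ref_t) or not (
            np.allclose(r.t_obs, ref_t) and np.allclose(r.biomass_obs, ref_y)
        ):
            raise ValueError("results were fitted to different observation series")
    order = sorted(results, key=lambda r: (r.aic, r.k, r.ssr))
    best_aic = order[0].aic
    return [
        {
            "rank": i + 1,
            "model": r.model_id.value,
            "aic": r.aic,
            "delta_aic": r.aic - best_aic,
            "k": r.k,
            "ssr": r.ssr,
            "converged": r.converged,
        }
        for i, r in enumerate(order)
    ]
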