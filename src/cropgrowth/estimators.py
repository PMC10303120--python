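"""Scikit-learn style estimators for the growth-model library.

Each growth model is exposed as a regressor with the familiar
``fit(X, y)`` / ``predict(X)`` contract, where ``X`` is the observation
time in days (a single column) and ``y`` the biomass series (kg m⁻²).
This lets the models participate in sklearn model selection and
pipelines; the underlying machinery is :func:`cropgrowth.fitting.fit_model`.

Fitted attributes follow the sklearn convention of a trailing
underscore: ``estimates_`` (free-parameter estimates), ``params_`` (the
full fitted parameter record), ``ssr_``, ``aic_``, ``converged_`` and
``result_`` (the complete :class:`~cropgrowth.fitting.FitResult`).

>>> est = LogisticGrowth()
>>> est.fit(t[:, None], biomass)       # doctest: +SKIP
>>> est.predict(t_new[:, None])        # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .fitting import FitSpec, compare_models, fit_model
from .params import ModelId, TemperatureResponseParams
from .simulate import SolverSettings, integrate_model


def _as_time_column(X) -> np.ndarray:
    X = check_array(X, ensure_2d=False, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError(
                f"expected a single time column, got {X.shape[1]} columns"
            )
        X = X[:, 0]
    return X


class GrowthCurveEstimator(RegressorMixin, BaseEstimator):
    """Base class: least-squares ODE growth-curve regression on time.

    Parameters
    ----------
    free : tuple of str, optional
        Quantities to estimate (default: all the model exposes).
    fixed : dict, optional
        Values for the quantities held fixed.
    bounds : dict, optional
        Per-quantity search bounds in user units.
    method : str
        "marq", "nelder-mead" or "pseudo".
    multistart : int
        Optimizer starts (extra starts are seeded Latin-hypercube draws).
    seed : int
        Seed for pseudo search / multistart.
    start : dict, optional
        Explicit initial guesses overriding the data-driven defaults.
    biomass_rescale : bool
        Divide biomass by 1000 inside the objective.
    drivers : dict, optional
        Smoothed environmental drivers (model-dependent).
    solver : SolverSettings, optional
    """

    _model_id: ModelId  # set by subclasses

    def __init__(
        self,
        free=None,
        fixed=None,
        bounds=None,
        method="marq",
        multistart=1,
        seed=0,
        start=None,
        biomass_rescale=True,
        drivers=None,
        solver=None,
    ):
        self.free = free
        self.fixed = fixed
        self.bounds = bounds
        self.method = method
        self.multistart = multistart
        self.seed = seed
        self.start = start
        self.biomass_rescale = biomass_rescale
        self.drivers = drivers
        self.solver = solver

    def _make_spec(self) -> FitSpec:
        return FitSpec(
            model_id=self._model_id,
            free=self.free,
            fixed=dict(self.fixed or {}),
            bounds=dict(self.bounds or {}),
            method=self.method,
            multistart=self.multistart,
            seed=self.seed,
            start=dict(self.start or {}),
            biomass_rescale=self.biomass_rescale,
            **self._extra_spec_kwargs(),
        )

    def _extra_spec_kwargs(self) -> dict:
        return {}

    def fit(self, X, y, soil_water=None):
        """Fit the model to times ``X`` (days) and biomass ``y``."""
        t = _as_time_column(X)
        y = check_array(y, ensure_2d=False, dtype=float)
        if t.shape != y.shape:
            raise ValueError("X and y have inconsistent lengths")
        order = np.argsort(t)
        t, y = t[order], y[order]
        if soil_water is not None:
            soil_water = np.asarray(soil_water, dtype=float)[order]
        spec = self._make_spec()
        result = fit_model(
            spec,
            t,
            y,
            soil_water_obs=soil_water,
            drivers=self.drivers,
            settings=self.solver or SolverSettings(),
        )
        self.result_ = result
        self.estimates_ = result.estimates
        self.params_ = result.params
        self.ssr_ = result.ssr
        self.aic_ = result.aic
        self.converged_ = result.converged
        self.n_features_in_ = 1
        self._t0_ = float(t[0])
        return self

    def predict(self, X):
        """Biomass at times ``X`` from the fitted trajectory.

        The fitted initial condition anchors at the first day seen during
        ``fit``; prediction integrates forward from there.
        """
        check_is_fitted(self, "params_")
        t = _as_time_column(X)
        t_sorted, inverse = np.unique(t, return_inverse=True)
        if t_sorted[0] < self._t0_:
            raise ValueError(
                f"cannot predict before the fitted initial day {self._t0_}"
            )
        grid = t_sorted
        prepend = grid[0] > self._t0_
        if prepend:
            grid = np.concatenate([[self._t0_], grid])
        traj = integrate_model(
            self._model_id,
            self.params_,
            grid,
            drivers=self.drivers,
            settings=self.solver or SolverSettings(),
        )
        values = traj.biomass[1:] if prepend else traj.biomass
        return values[inverse]


class LogisticGrowth(GrowthCurveEstimator):
    """Logistic growth: implicit (self-limiting) growth restriction."""

    _model_id = ModelId.LOGISTIC


class IrradianceGrowth(GrowthCurveEstimator):
    """Logistic growth with a seasonal day-length modulation of the rate."""

    _model_id = ModelId.IRRADIANCE


class TemperatureGrowth(GrowthCurveEstimator):
    """Logistic growth with the rate scaled by an enzyme-inactivation
    temperature response; requires a ``temperature`` driver (Kelvin)."""

    _model_id = ModelId.TEMPERATURE

    def __init__(
        self,
        free=None,
        fixed=None,
        bounds=None,
        method="marq",
        multistart=1,
        seed=0,
        start=None,
        biomass_rescale=True,
        drivers=None,
        solver=None,
        response=None,
    ):
        super().__init__(
            free=free,
            fixed=fixed,
            bounds=bounds,
            method=method,
            multistart=multistart,
            seed=seed,
            start=start,
            biomass_rescale=biomass_rescale,
            drivers=drivers,
            solver=solver,
        )
        self.response = response

    def _extra_spec_kwargs(self):
        return {"response": self.response or TemperatureResponseParams()}


class WaterBalanceGrowth(GrowthCurveEstimator):
    """Coupled soil-water/biomass model; requires a ``precipitation``
    driver and optionally co-fits soil-water observations.

    Defaults to 16 seeded multistart attempts — the 11-quantity water
    model has a rugged objective surface and a single Marquardt start
    from generic guesses frequently lands in a local optimum.
    """

    _model_id = ModelId.WATER

    def __init__(
        self,
        free=None,
        fixed=None,
        bounds=None,
        method="marq",
        multistart=16,
        seed=0,
        start=None,
        biomass_rescale=True,
        drivers=None,
        solver=None,
        soil_water_weight="auto",
    ):
        super().__init__(
            free=free,
            fixed=fixed,
            bounds=bounds,
            method=method,
            multistart=multistart,
            seed=seed,
            start=start,
            biomass_rescale=biomass_rescale,
            drivers=drivers,
            solver=solver,
        )
        self.soil_water_weight = soil_water_weight

    def _extra_spec_kwargs(self):
        return {"soil_water_weight": self.soil_water_weight}

    def predict_soil_water(self, X):
        """Soil-water trajectory values at times ``X``."""
        check_is_fitted(self, "params_")
        t = _as_time_column(X)
        t_sorted, inverse = np.unique(t, return_inverse=True)
        grid = t_sorted
        prepend = grid[0] > self._t0_
        if prepend:
            grid = np.concatenate([[self._t0_], grid])
        traj = integrate_model(
            self._model_id,
            self.params_,
            grid,
            drivers=self.drivers,
            settings=self.solver or SolverSettings(),
        )
        values = traj.soil_water[1:] if prepend else traj.soil_water
        return values[inverse]


ESTIMATOR_CLASSES = {
    ModelId.LOGISTIC: LogisticGrowth,
    ModelId.IRRADIANCE: IrradianceGrowth,
    ModelId.TEMPERATURE: TemperatureGrowth,
    ModelId.WATER: WaterBalanceGrowth,
}


def rank_models(fitted_estimators):
    """AIC ranking of fitted estimators on one series (see
    :func:`cropgrowth.fitting.compare_models`)."""
    return compare_models([est.result_ for est in fitted_estimators])
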