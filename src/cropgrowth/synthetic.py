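"""Synthetic trial generation: weather, genotype panels, and forward-
simulated growth series.

The generator stands in for a crop-simulation-platform export: a panel of
genotypes (parameter records drawn around panel means), a grid of
location-by-year trials with seeded daily weather, and noise-free daily
trajectories obtained by forward integration of a chosen growth model.
Biomass is noise-free by default — fitting is then evaluated under the
most discriminatory conditions — with optional additive Gaussian noise
for robustness checks.

Reproducibility contract: one master seed deterministically derives every
per-cell seed by hashing (location, year, genotype), so any subset of a
trial grid regenerates identically regardless of iteration order.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .drivers import (
    EnvironmentSeries,
    precipitation_driver,
    temperature_driver,
)
from .models import required_drivers
from .params import ModelId, WaterModelParams
from .simulate import SolverSettings, Trajectory, day_grid, integrate_model

#: default growing-season length in days (typical of Australian wheat)
DEFAULT_SEASON_DAYS = 150


def derive_seed(master_seed: int, *tokens) -> int:
    """Stable sub-seed < 2^31 from a master seed and identifying tokens."""
    key = ":".join([str(master_seed), *map(str, tokens)]).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


@dataclass(frozen=True)
class LocationProfile:
    """Climate summary a weather series is generated from.

    Temperature is a seasonal sinusoid plus AR(1) noise; rainfall follows
    a two-state (wet/dry) Markov occurrence chain with gamma-distributed
    wet-day amounts.
    """

    name: str
    mean_temp: float  # mean annual temperature, °C
    seasonal_amplitude: float  # half peak-to-trough seasonal swing, °C
    temp_noise_sd: float  # sd of the AR(1) temperature noise, °C
    p_wet_given_wet: float  # persistence of wet spells
    p_wet_given_dry: float  # onset probability of rain after a dry day
    mean_wet_rainfall: float  # mean rainfall on wet days, mm
    diurnal_half_range: float = 5.0  # (t_max − t_min)/2, °C
    ar1: float = 0.6  # temperature noise autocorrelation
    gamma_shape: float = 0.8  # wet-day rainfall gamma shape
    phase_day: float = 0.0  # day offset of the seasonal sinusoid

    def __post_init__(self) -> None:
        for p in ("p_wet_given_wet", "p_wet_given_dry"):
            if not 0 <= getattr(self, p) <= 1:
                raise ValueError(f"{p} must lie in [0, 1]")
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal_amplitude must be >= 0")
        if self.mean_wet_rainfall <= 0:
            raise ValueError("mean_wet_rainfall must be > 0")
        if not 0 <= self.ar1 < 1:
            raise ValueError("ar1 must lie in [0, 1)")

    @property
    def stationary_wet_probability(self) -> float:
        """Long-run wet-day frequency of the two-state occurrence chain."""
        denom = 1.0 - self.p_wet_given_wet + self.p_wet_given_dry
        return self.p_wet_given_dry / denom if denom > 0 else 1.0


#: four semi-arid to temperate profiles spanning the climatic range of the
#: Australian wheat belt (hot/summer-dominant rain to mild/winter rain)
AUSTRALIAN_PROFILES: dict[str, LocationProfile] = {
    "emerald": LocationProfile(
        "emerald", 22.0, 6.0, 2.0, 0.45, 0.12, 8.0
    ),
    "merredin": LocationProfile(
        "merredin", 17.5, 7.0, 2.0, 0.40, 0.15, 5.0
    ),
    "narrabri": LocationProfile(
        "narrabri", 19.0, 8.0, 2.5, 0.40, 0.14, 7.0
    ),
    "yanco": LocationProfile(
        "yanco", 16.5, 7.5, 2.0, 0.42, 0.16, 5.5
    ),
}


def generate_weather(
    profile: LocationProfile, n_days: int, seed: int
) -> EnvironmentSeries:
    """Seeded daily weather series for one trial.

    T_avg(d) = mean + amplitude·sin(2π(d + phase)/365) + AR(1) noise,
    T_min/T_max = T_avg ∓ diurnal half-range; rainfall occurrence follows
    the profile's Markov chain with gamma wet-day amounts.
    """
    if n_days < 30:
        raise ValueError(f"need at least 30 days of weather, got {n_days}")
    rng = np.random.default_rng(seed)
    days = np.arange(n_days)
    seasonal = profile.mean_temp + profile.seasonal_amplitude * np.sin(
        2.0 * np.pi * (days + profile.phase_day) / 365.0
    )
    noise = np.zeros(n_days)
    if profile.temp_noise_sd > 0:
        innov_sd = profile.temp_noise_sd * np.sqrt(1.0 - profile.ar1**2)
        eps = rng.normal(0.0, innov_sd, n_days)
        noise[0] = rng.normal(0.0, profile.temp_noise_sd)
        for i in range(1, n_days):
            noise[i] = profile.ar1 * noise[i - 1] + eps[i]
    t_avg = seasonal + noise

    wet = np.zeros(n_days, dtype=bool)
    wet[0] = rng.random() < profile.stationary_wet_probability
    u = rng.random(n_days)
    for i in range(1, n_days):
        p = profile.p_wet_given_wet if wet[i - 1] else profile.p_wet_given_dry
        wet[i] = u[i] < p
    rain = np.zeros(n_days)
    n_wet = int(wet.sum())
    if n_wet:
        shape = profile.gamma_shape
        rain[wet] = rng.gamma(
            shape, profile.mean_wet_rainfall / shape, n_wet
        )

    return EnvironmentSeries(
        day=days,
        t_avg=t_avg,
        t_min=t_avg - profile.diurnal_half_range,
        t_max=t_avg + profile.diurnal_half_range,
        precipitation=rain,
    )


# ---------------------------------------------------------------------------
# genotype panels

@dataclass
class GenotypePanel:
    """Per-genotype parameter records for one model, drawn around panel
    means with a common coefficient of variation."""

    model_id: ModelId
    ids: list[str]
    records: list
    means: object
    cv: float
    seed: int

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, genotype_id: str):
        return self.records[self.ids.index(genotype_id)]


#: fields never perturbed across genotypes (fixed temperature response)
_NON_GENETIC_FIELDS = {"response"}

#: fields bounded in (0, 1]; genotypic variation is applied on the logit
#: scale so draws cannot leave the admissible range
_LOGIT_FIELDS = {"uptake_exponent", "infiltration_fraction"}

#: fields that may take either sign; perturbed additively
_SIGNED_FIELDS = {"amplitude", "phase"}


def _perturb_record(means, cv: float, rng: np.random.Generator):
    """One genotype draw: log-normal (mean-preserving) for positive
    quantities, logit-normal for (0,1]-bounded ones, additive normal for
    signed ones."""
    if cv == 0:
        return means
    sigma = float(np.sqrt(np.log1p(cv**2)))
    values = {}
    for f in fields(means):
        x = getattr(means, f.name)
        if f.name in _NON_GENETIC_FIELDS:
            values[f.name] = x
        elif f.name in _LOGIT_FIELDS:
            xc = float(np.clip(x, 1e-9, 1 - 1e-9))
            logit = np.log(xc / (1 - xc)) + rng.normal(0.0, sigma)
            values[f.name] = float(1.0 / (1.0 + np.exp(-logit)))
        elif f.name in _SIGNED_FIELDS:
            values[f.name] = float(x + rng.normal(0.0, cv * max(abs(x), 1e-3)))
        else:
            values[f.name] = float(
                x * rng.lognormal(-0.5 * sigma**2, sigma)
            )
    return type(means)(**values)


def generate_genotype_panel(
    model_id: ModelId, n: int, means, cv: float, seed: int
) -> GenotypePanel:
    """Draw ``n`` genotype parameter records around ``means``.

    ``cv`` is the coefficient of variation of the (log-normal) genotypic
    distribution of each positive parameter; ``cv=0`` yields ``n``
    identical genotypes.  Records violating the model's own invariants
    (possible at large cv, e.g. an initial biomass drawn above the
    carrying capacity) are redrawn.
    """
    if n < 1:
        raise ValueError("panel size must be >= 1")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    model_id = ModelId(model_id)
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n)))
    ids, records = [], []
    for i in range(n):
        for _attempt in range(100):
            try:
                rec = _perturb_record(means, cv, rng)
                break
            except ValueError:
                continue
        else:
            raise ValueError(
                "could not draw a valid genotype record in 100 attempts; "
                "reduce cv or adjust the means"
            )
        ids.append(f"g{i + 1:0{width}d}")
        records.append(rec)
    return GenotypePanel(
        model_id=model_id, ids=ids, records=records, means=means, cv=cv, seed=seed
    )


# ---------------------------------------------------------------------------
# trial grids

@dataclass
class TrialSet:
    """Full-factorial catalogue of (location, year, genotype) trials."""

    panel: GenotypePanel
    profiles: list[LocationProfile]
    years: list[int]
    season_length: int
    seed: int
    weather: dict[tuple[str, int], EnvironmentSeries] = field(default_factory=dict)
    trajectories: dict[tuple[str, int, str], Trajectory] = field(
        default_factory=dict
    )

    def __len__(self) -> int:
        return len(self.trajectories)

    def catalogue(self) -> pd.DataFrame:
        rows = [
            {
                "location": loc,
                "year": year,
                "genotype": gid,
                "n_days": len(traj),
                "final_biomass": float(traj.biomass[-1]),
            }
            for (loc, year, gid), traj in sorted(self.trajectories.items())
        ]
        return pd.DataFrame(rows)

    def write(self, root) -> None:
        """Directory tree: trials/<loc>/<year>/<genotype>.csv,
        weather/<loc>/<year>.csv, plus catalogue.csv."""
        from .io import write_trajectory_csv, write_weather_csv

        root = Path(root)
        for (loc, year), series in self.weather.items():
            path = root / "weather" / loc / f"{year}.csv"
            path.parent.mkdir(parents=True, exist_ok=True)
            write_weather_csv(series, path)
        for (loc, year, gid), traj in self.trajectories.items():
            path = root / "trials" / loc / str(year) / f"{gid}.csv"
            path.parent.mkdir(parents=True, exist_ok=True)
            write_trajectory_csv(traj, path)
        self.catalogue().to_csv(root / "catalogue.csv", index=False)


def generate_trial_set(
    panel: GenotypePanel,
    profiles,
    years: int,
    season_length: int = DEFAULT_SEASON_DAYS,
    seed: int = 0,
    noise_sd: float = 0.0,
    settings: SolverSettings | None = None,
) -> TrialSet:
    """Forward-simulate the panel over a location-by-year grid.

    For every cell, a seeded weather series is generated, smoothed into
    drivers, and each genotype's model is integrated over the season.
    The trajectory count equals |genotypes| × |locations| × |years|.
    ``noise_sd`` > 0 adds Gaussian observation noise to biomass
    (default 0: noise-free).
    """
    profiles = list(profiles)
    year_list = list(range(1, years + 1)) if isinstance(years, int) else list(years)
    settings = settings or SolverSettings()
    trial_set = TrialSet(
        panel=panel,
        profiles=profiles,
        years=year_list,
        season_length=season_length,
        seed=seed,
    )
    t_grid = day_grid(season_length)
    needed = required_drivers(panel.model_id)
    for profile in profiles:
        for year in year_list:
            wseed = derive_seed(seed, "weather", profile.name, year)
            series = generate_weather(profile, season_length + 1, wseed)
            trial_set.weather[(profile.name, year)] = series
            drivers = {}
            if "temperature" in needed:
                drivers["temperature"] = temperature_driver(series)
            if "precipitation" in needed:
                drivers["precipitation"] = precipitation_driver(series)
            for gid, rec in zip(panel.ids, panel.records):
                traj = integrate_model(
                    panel.model_id, rec, t_grid, drivers=drivers, settings=settings
                )
                if noise_sd > 0:
                    nseed = derive_seed(seed, "noise", profile.name, year, gid)
                    noise = np.random.default_rng(nseed).normal(
                        0.0, noise_sd, len(traj)
                    )
                    traj = Trajectory(
                        t=traj.t,
                        biomass=np.maximum(traj.biomass + noise, 0.0),
                        soil_water=traj.soil_water,
                        model_id=traj.model_id,
                        params=traj.params,
                    )
                trial_set.trajectories[(profile.name, year, gid)] = traj
    return trial_set


# ---------------------------------------------------------------------------
# the end-of-season "bump" scenario

#: water-model parameters used by the bump scenario: a fast-drying soil
#: and a noticeable maintenance cost, so a mid-season dry spell halts and
#: then reverses biomass growth until rain returns
BUMP_PARAMS = WaterModelParams(
    precip_conversion=1.0,
    infiltration_fraction=0.3,
    infiltration_constant=10.0,
    uptake_rate=0.12,
    half_saturation=8.0,
    uptake_exponent=0.8,
    drying_rate=0.08,
    conversion_efficiency=1.0,
    maintenance_rate=0.02,
    initial_soil_water=30.0,
    initial_biomass=0.01,
)


@dataclass
class BumpScenario:
    """A water-limited trial whose biomass re-accelerates after late rain."""

    weather: EnvironmentSeries
    trajectory: Trajectory
    params: WaterModelParams
    drivers: dict
    rain_day: int


def make_bump_scenario(
    seed: int = 0,
    season_length: int = DEFAULT_SEASON_DAYS,
    dry_start: int = 60,
    rain_day: int = 105,
    with_rain_event: bool = True,
) -> BumpScenario:
    """Construct the late-season "bump" fixture.

    Rainfall is moderate early on, absent during a dry spell starting at
    ``dry_start``, and (unless ``with_rain_event`` is False, the control
    scenario) returns as a heavy event around ``rain_day``.  Under
    :data:`BUMP_PARAMS` the simulated biomass stalls in the drought and
    shows a clear growth bump after the rain — a pattern the logistic
    model cannot produce.
    """
    rng = np.random.default_rng(seed)
    n_days = season_length + 1
    days = np.arange(n_days)
    rain = np.zeros(n_days)
    early = days < dry_start
    wet_early = rng.random(early.sum()) < 0.45
    rain[:dry_start][wet_early] = rng.gamma(1.2, 7.0 / 1.2, int(wet_early.sum()))
    if with_rain_event:
        event = (days >= rain_day) & (days < rain_day + 8)
        rain[event] = rng.gamma(4.0, 18.0 / 4.0, int(event.sum()))
        late = days >= rain_day + 8
        wet_late = rng.random(late.sum()) < 0.3
        rain[late] = np.where(
            wet_late, rng.gamma(1.2, 5.0 / 1.2, int(late.sum())), 0.0
        )
    t_base = 16.0 + 4.0 * np.sin(2 * np.pi * days / 365.0) + rng.normal(0, 1.5, n_days)
    weather = EnvironmentSeries(
        day=days,
        t_avg=t_base,
        t_min=t_base - 5.0,
        t_max=t_base + 5.0,
        precipitation=rain,
    )
    drivers = {"precipitation": precipitation_driver(weather)}
    traj = integrate_model(
        ModelId.WATER, BUMP_PARAMS, day_grid(season_length), drivers=drivers
    )
    return BumpScenario(
        weather=weather,
        trajectory=traj,
        params=BUMP_PARAMS,
        drivers=drivers,
        rain_day=rain_day,
    )
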