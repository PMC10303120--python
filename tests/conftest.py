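"""Shared fixtures: reference parameter sets, seeded weather, trajectories.

Expensive forward simulations are session-scoped so the suite integrates
each reference trajectory once.
"""

import numpy as np
import pytest

import cropgrowth as cg

#: reference soil-water parameter set used throughout (a published
#: single-trial wheat fit; also the anchor of the acceptance targets)
REFERENCE_WATER_PARAMS = cg.WaterModelParams(
    precip_conversion=1.061,
    infiltration_fraction=5.521e-2,
    infiltration_constant=3.618e2,
    uptake_rate=7.824e-2,
    half_saturation=1.095,
    uptake_exponent=5.318e-1,
    drying_rate=1.320e-3,
    conversion_efficiency=1.108,
    maintenance_rate=1.150e-2,
    initial_soil_water=1.880,
    initial_biomass=5.584e-3,
)

WEATHER_SEED = 42
SEASON_DAYS = 150


@pytest.fixture(scope="session")
def water_params():
    return REFERENCE_WATER_PARAMS


@pytest.fixture(scope="session")
def season_weather():
    """One seeded 151-day weather series from the semi-arid profile."""
    return cg.generate_weather(
        cg.AUSTRALIAN_PROFILES["emerald"], SEASON_DAYS + 1, WEATHER_SEED
    )


@pytest.fixture(scope="session")
def rain_driver(season_weather):
    return cg.precipitation_driver(season_weather)


@pytest.fixture(scope="session")
def temp_driver(season_weather):
    return cg.temperature_driver(season_weather)


@pytest.fixture(scope="session")
def water_trajectory(water_params, rain_driver):
    """Noise-free forward simulation of the reference water-model trial."""
    return cg.integrate_model(
        "water",
        water_params,
        cg.day_grid(SEASON_DAYS),
        drivers={"precipitation": rain_driver},
    )


@pytest.fixture(scope="session")
def logistic_params():
    return cg.LogisticParams(
        growth_rate=0.09, carrying_capacity=1.2, initial_biomass=0.004
    )


@pytest.fixture(scope="session")
def logistic_trajectory(logistic_params):
    return cg.integrate_model(
        "logistic", logistic_params, cg.day_grid(SEASON_DAYS)
    )


@pytest.fixture(scope="session")
def bump_scenario():
    return cg.make_bump_scenario(seed=0)
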