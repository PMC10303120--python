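"""Parameter records for the four growth models.

Each model is parameterized by a frozen dataclass that validates its
biological constraints at construction time.  Field names are descriptive;
units are documented per field.  Records are immutable so they can be
shared safely between the simulation engine and the fitting machinery;
``replace`` (from :mod:`dataclasses`) produces modified copies.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, fields


class ModelId(str, enum.Enum):
    """Closed enumeration of the model library."""

    LOGISTIC = "logistic"
    IRRADIANCE = "irradiance"
    TEMPERATURE = "temperature"
    WATER = "water"


def _require_finite(obj) -> None:
    for f in fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, (int, float)) and not math.isfinite(v):
            raise ValueError(f"{type(obj).__name__}.{f.name} must be finite, got {v!r}")


@dataclass(frozen=True)
class LogisticParams:
    """Logistic growth: dM/dt = r·M·(1 − M/M_max).

    Attributes
    ----------
    growth_rate : float
        Intrinsic growth rate r (day⁻¹), non-negative.
    carrying_capacity : float
        Biomass ceiling M_max (kg m⁻²), positive.
    initial_biomass : float
        Biomass M₀ at the first observed day (kg m⁻²),
        with 0 < M₀ < M_max.
    """

    growth_rate: float
    carrying_capacity: float
    initial_biomass: float

    def __post_init__(self) -> None:
        _require_finite(self)
        if self.growth_rate < 0:
            raise ValueError(f"growth_rate must be >= 0, got {self.growth_rate}")
        if self.carrying_capacity <= 0:
            raise ValueError(
                f"carrying_capacity must be > 0, got {self.carrying_capacity}"
            )
        if not 0 < self.initial_biomass < self.carrying_capacity:
            raise ValueError(
                "initial_biomass must lie strictly between 0 and carrying_capacity, "
                f"got {self.initial_biomass} (capacity {self.carrying_capacity})"
            )


@dataclass(frozen=True)
class IrradianceParams(LogisticParams):
    """Logistic growth with a seasonal (day-length) modulation of the rate.

    The intrinsic rate is replaced by r + A·sin(2π(t + φ)/365).  Amplitude
    and phase may take either sign.  A warning (not an error) is emitted
    when |A| exceeds r, since the effective rate then goes negative for
    part of the year; transient negative growth is a legitimate regime.

    Attributes
    ----------
    amplitude : float
        Seasonal driver amplitude A (day⁻¹), any sign.
    phase : float
        Phase shift φ (day), any sign.
    """

    amplitude: float = 0.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.growth_rate - abs(self.amplitude) < 0:
            warnings.warn(
                "irradiance amplitude exceeds the base growth rate; the "
                "effective rate is negative for part of the season",
                stacklevel=3,
            )


@dataclass(frozen=True)
class TemperatureResponseParams:
    """Enzyme-inactivation temperature response (fraction of peak activity).

    f(T) = 1 / (1 + exp(T_AL/T − T_AL/T_L) + exp(T_AH/T_H − T_AH/T))

    The defaults approximate the cardinal temperatures of wheat and are
    conventionally held fixed (no genotypic variation).

    Attributes
    ----------
    t_low, t_high : float
        Lower / upper boundary of the tolerance range (K).
    arrhenius_low, arrhenius_high : float
        Arrhenius temperatures controlling the steepness of the decline
        at the lower / upper boundary (K).
    """

    t_low: float = 292.0
    t_high: float = 303.0
    arrhenius_low: float = 2.0e4
    arrhenius_high: float = 6.0e4

    def __post_init__(self) -> None:
        _require_finite(self)
        if not 0 < self.t_low < self.t_high:
            raise ValueError(
                f"need 0 < t_low < t_high, got ({self.t_low}, {self.t_high})"
            )
        if self.arrhenius_low <= 0 or self.arrhenius_high <= 0:
            raise ValueError("Arrhenius temperatures must be positive")


@dataclass(frozen=True)
class TemperatureModelParams(LogisticParams):
    """Logistic growth with the rate modulated by ambient temperature.

    dM/dt = r·f(T(t))·M·(1 − M/M_max), with T(t) supplied as a smoothed
    driver at simulation time.
    """

    response: TemperatureResponseParams = field(
        default_factory=TemperatureResponseParams
    )


@dataclass(frozen=True)
class WaterModelParams:
    """Coupled soil-water / biomass model (leaky-bucket soil, saturating uptake).

    dW/dt = p·((M + K·q)/(M + K))·P(t) − c·(W/(W + n))·M^v − R·W
    dM/dt = g·c·(W/(W + n))·M^v − m·M

    Attributes
    ----------
    precip_conversion : float
        p — precipitation-to-soil-water conversion (m⁻¹).
    infiltration_fraction : float
        q — fraction of precipitation infiltrating barren soil
        (dimensionless, 0 ≤ q ≤ 1).
    infiltration_constant : float
        K — crop-related infiltration constant (kg m⁻²); large biomass
        raises the infiltration factor from q toward 1.
    uptake_rate : float
        c — soil-water uptake capacity of the crop (kg⁻¹ ml m⁻¹ day⁻¹).
    half_saturation : float
        n — Michaelis–Menten half-rate of the uptake response (ml m⁻³).
    uptake_exponent : float
        v — scaling between uptake surface and maintained volume
        (dimensionless, 0 < v ≤ 1).
    drying_rate : float
        R — leaky-bucket soil drying rate (day⁻¹).
    conversion_efficiency : float
        g — soil-water to biomass conversion factor (kg ml⁻¹ m).
    maintenance_rate : float
        m — maintenance respiration rate (day⁻¹); the only term that can
        drive biomass down.
    initial_soil_water : float
        W₀ (ml m⁻³).
    initial_biomass : float
        M₀ (kg m⁻²).
    """

    precip_conversion: float
    infiltration_fraction: float
    infiltration_constant: float
    uptake_rate: float
    half_saturation: float
    uptake_exponent: float
    drying_rate: float
    conversion_efficiency: float
    maintenance_rate: float
    initial_soil_water: float
    initial_biomass: float

    def __post_init__(self) -> None:
        _require_finite(self)
        nonneg = (
            "precip_conversion",
            "infiltration_fraction",
            "infiltration_constant",
            "uptake_rate",
            "half_saturation",
            "drying_rate",
            "conversion_efficiency",
            "maintenance_rate",
            "initial_soil_water",
            "initial_biomass",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.infiltration_fraction > 1:
            raise ValueError(
                f"infiltration_fraction must be <= 1, got {self.infiltration_fraction}"
            )
        if not 0 < self.uptake_exponent <= 1:
            raise ValueError(
                f"uptake_exponent must lie in (0, 1], got {self.uptake_exponent}"
            )


PARAM_CLASSES = {
    ModelId.LOGISTIC: LogisticParams,
    ModelId.IRRADIANCE: IrradianceParams,
    ModelId.TEMPERATURE: TemperatureModelParams,
    ModelId.WATER: WaterModelParams,
}
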