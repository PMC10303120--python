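"""Readers and writers for trajectory and weather tables.

Formats are deliberately plain: headered CSV for trajectories
(``t, biomass[, soil_water]``) and weather (``day, tmin, tmax, tavg,
rain``; °C and mm/day), plus a reader for APSIM-style ``.met`` weather
files (whitespace-separated, a field-name line and a units line, fields
``year day maxt mint rain``).  Validation failures cite the offending
line number of the input file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .drivers import EnvironmentSeries
from .simulate import Trajectory


@dataclass
class ObservationSeries:
    """Observed biomass (and optional soil water) on a day grid."""

    t: np.ndarray
    biomass: np.ndarray
    soil_water: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.t)


def _check_numeric(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    """Coerce columns to float; report non-numeric cells by file line."""
    out = df.copy()
    for col in columns:
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna()
        if bad.any():
            # +2: 1-based lines plus the header row
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(
                f"{path}: non-numeric value {out[col][bad].iloc[0]!r} in "
                f"column '{col}' at line {line}"
            )
        if coerced.isna().any():
            line = int(np.flatnonzero(coerced.isna().to_numpy())[0]) + 2
            raise ValueError(f"{path}: missing value in column '{col}' at line {line}")
        out[col] = coerced
    return out


def read_trajectory_csv(path) -> ObservationSeries:
    """Read an observation series (columns ``t, biomass[, soil_water]``)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"t", "biomass"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    cols = ["t", "biomass"] + (["soil_water"] if "soil_water" in df.columns else [])
    df = _check_numeric(df, cols, path)
    t = df["t"].to_numpy()
    diffs = np.diff(t)
    if np.any(diffs == 0):
        line = int(np.flatnonzero(diffs == 0)[0]) + 3  # second of the pair
        raise ValueError(f"{path}: duplicate t value at line {line}")
    if np.any(diffs < 0):
        line = int(np.flatnonzero(diffs < 0)[0]) + 3
        raise ValueError(f"{path}: t values not sorted at line {line}")
    return ObservationSeries(
        t=t,
        biomass=df["biomass"].to_numpy(),
        soil_water=df["soil_water"].to_numpy() if "soil_water" in cols else None,
    )


def write_trajectory_csv(traj: Trajectory | ObservationSeries, path) -> None:
    """Write a trajectory/observation series; round-trips at full precision."""
    data = {"t": traj.t, "biomass": traj.biomass}
    sw = getattr(traj, "soil_water", None)
    if sw is not None:
        data["soil_water"] = sw
    pd.DataFrame(data).to_csv(path, index=False)


_WEATHER_COLUMNS = ["day", "tmin", "tmax", "tavg", "rain"]


def _weather_from_frame(df: pd.DataFrame, path) -> EnvironmentSeries:
    if np.any(df["rain"].to_numpy() < 0):
        line = int(np.flatnonzero(df["rain"].to_numpy() < 0)[0]) + 2
        raise ValueError(f"{path}: negative rainfall at line {line}")
    return EnvironmentSeries(
        day=df["day"].to_numpy(),
        t_min=df["tmin"].to_numpy(),
        t_max=df["tmax"].to_numpy(),
        t_avg=df["tavg"].to_numpy(),
        precipitation=df["rain"].to_numpy(),
    )


def read_weather(path, dialect: str = "csv") -> EnvironmentSeries:
    """Read a daily weather series.

    ``dialect="csv"``: headered CSV with columns ``day, tmin, tmax, tavg,
    rain``.  ``dialect="met"``: APSIM-style whitespace-separated file with
    a field-name line followed by a units line (entries parenthesised,
    e.g. ``() (oC) (mm)``); fields ``year, day, maxt, mint, rain`` are
    mapped and (year, day-of-year) flattened to a running day index.
    """
    path = Path(path)
    if dialect == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = set(_WEATHER_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing weather columns {sorted(missing)}")
        df = _check_numeric(df, _WEATHER_COLUMNS, path)
        return _weather_from_frame(df, path)
    if dialect == "met":
        return _read_met(path)
    raise ValueError(f"unknown weather dialect {dialect!r}")


def _read_met(path) -> EnvironmentSeries:
    path = Path(path)
    lines = path.read_text().splitlines()
    # skip leading comment/metadata lines (APSIM uses '!' comments and
    # 'key = value' site metadata) down to the column-name line
    idx = 0
    while idx < len(lines):
        s = lines[idx].strip()
        if s and not s.startswith("!") and "=" not in s:
            break
        idx += 1
    if idx + 1 >= len(lines):
        raise ValueError(f"{path}: no header/units lines found")
    names = lines[idx].split()
    units = lines[idx + 1].split()
    if len(units) != len(names) or not all(
        u.startswith("(") and u.endswith(")") for u in units
    ):
        raise ValueError(
            f"{path}: line {idx + 2} is not a units line matching the "
            f"{len(names)} header fields"
        )
    required = {"year", "day", "maxt", "mint", "rain"}
    if not required <= set(names):
        raise ValueError(
            f"{path}: met header must contain {sorted(required)}, got {names}"
        )
    rows = []
    for ln, raw in enumerate(lines[idx + 2 :], start=idx + 3):
        if not raw.strip() or raw.strip().startswith("!"):
            continue
        parts = raw.split()
        if len(parts) != len(names):
            raise ValueError(
                f"{path}: line {ln} has {len(parts)} fields, expected {len(names)}"
            )
        try:
            rows.append({n: float(v) for n, v in zip(names, parts)})
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric value at line {ln}") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    df = pd.DataFrame(rows)
    if np.any(df["rain"].to_numpy() < 0):
        raise ValueError(f"{path}: negative rainfall")
    # flatten (year, day-of-year) to a running index from the first record
    year = df["year"].to_numpy()
    doy = df["day"].to_numpy()
    day_index = np.zeros(len(df))
    offset = 0.0
    for i in range(1, len(df)):
        if year[i] != year[i - 1]:
            days_in_year = 366.0 if _is_leap(int(year[i - 1])) else 365.0
            offset += days_in_year
        day_index[i] = doy[i] + offset - doy[0]
    t_avg = (df["maxt"].to_numpy() + df["mint"].to_numpy()) / 2.0
    return EnvironmentSeries(
        day=day_index,
        t_min=df["mint"].to_numpy(),
        t_max=df["maxt"].to_numpy(),
        t_avg=t_avg,
        precipitation=df["rain"].to_numpy(),
    )


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def write_weather_csv(series: EnvironmentSeries, path) -> None:
    t_min = series.t_min if series.t_min is not None else series.t_avg
    t_max = series.t_max if series.t_max is not None else series.t_avg
    pd.DataFrame(
        {
            "day": series.day,
            "tmin": t_min,
            "tmax": t_max,
            "tavg": series.t_avg,
            "rain": series.precipitation,
        }
    ).to_csv(path, index=False)


def write_fit_result(result, out_dir) -> None:
    """Write a fit as a flat key-value table plus a residuals CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        ("model", result.model_id.value),
        ("method", result.method),
        ("converged", result.converged),
        ("n_obs", result.n_obs),
        ("k", result.k),
        ("ssr", repr(result.ssr)),
        ("aic", repr(result.aic)),
    ]
    rows += [(f"estimate.{n}", repr(v)) for n, v in result.estimates.items()]
    rows += [(f"fixed.{n}", repr(v)) for n, v in result.fixed.items()]
    (out_dir / "fit.txt").write_text(
        "\n".join(f"{k} = {v}" for k, v in rows) + "\n"
    )
    frames = []
    for state, series in result.residuals.items():
        frames.append(
            pd.DataFrame(
                {"t": series.t, "residual": series.residuals, "state": state}
            )
        )
    pd.concat(frames).to_csv(out_dir / "residuals.csv", index=False)
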