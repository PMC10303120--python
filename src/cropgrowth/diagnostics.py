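"""Residual autocorrelation diagnostics.

Least-squares fits of dynamic models typically leave serially correlated
residuals when the model misses structure in the data.  Two standard
instruments are reported: the Durbin–Watson statistic (≈2 for serially
uncorrelated residuals, →0 under positive lag-1 correlation, →4 under
negative) and the partial autocorrelation function with the conventional
±2/√n reference band.  No p-values are attached — on noise-free data the
statistics flag structure, not significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.stattools import durbin_watson as _sm_durbin_watson
from statsmodels.tsa.stattools import pacf as _sm_pacf


@dataclass
class DiagnosticsReport:
    """PACF values at lags 1..L, the ±2/√n band, and the DW statistic."""

    lags: np.ndarray
    pacf: np.ndarray
    band: float
    dw: float
    n: int

    def to_rows(self):
        """(lag, pacf, band) rows for CSV writing."""
        return [
            (int(l), float(p), self.band) for l, p in zip(self.lags, self.pacf)
        ]


def durbin_watson(residuals) -> float:
    """Durbin–Watson statistic Σ(rᵢ − rᵢ₋₁)² / Σ rᵢ²."""
    r = np.asarray(residuals, dtype=float)
    if len(r) < 2:
        raise ValueError("need at least 2 residuals")
    if not np.any(r != 0):
        raise ValueError("Durbin-Watson undefined for all-zero residuals")
    return float(_sm_durbin_watson(r))


def pacf(residuals, max_lag: int):
    """Partial autocorrelations at lags 1..max_lag.

    Computed by the Durbin–Levinson recursion on biased (1/n) sample
    autocovariances (the Yule–Walker "mle" convention), which keeps the
    implied autoregressive system positive definite.
    """
    r = np.asarray(residuals, dtype=float)
    if len(r) <= max_lag + 1:
        raise ValueError(
            f"series of length {len(r)} too short for max_lag={max_lag}"
        )
    if np.std(r) == 0:
        raise ValueError("PACF undefined for a zero-variance series")
    values = _sm_pacf(r, nlags=max_lag, method="ywm")
    return values[1:]  # drop the trivial lag-0 entry (always 1)


def diagnose(residuals, max_lag: int = 20) -> DiagnosticsReport:
    """Full report: PACF with reference band plus Durbin–Watson."""
    r = np.asarray(residuals, dtype=float)
    max_lag = min(max_lag, len(r) - 2)
    return DiagnosticsReport(
        lags=np.arange(1, max_lag + 1),
        pacf=pacf(r, max_lag),
        band=2.0 / np.sqrt(len(r)),
        dw=durbin_watson(r),
        n=len(r),
    )
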