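"""Series preparation for the causal analysis.

Four steps, applied per series as its preprocessing plan dictates:
seasonal adjustment (classical additive decomposition with a centered
moving-average trend and zero-sum monthly factors — an ARIMA-model-based
adjuster would also fit here, but the causal pipeline only needs the
seasonal component removed), linear detrending, an augmented Dickey-Fuller
stationarity check, and binary symbolization. Change symbolization writes 1
where the next value is strictly greater (ties give 0) and shortens the
series by one; event symbolization marks months with at least one event and
preserves length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from statsmodels.tsa.seasonal import seasonal_decompose
from statsmodels.tsa.stattools import adfuller

__all__ = [
    "SymbolicSeries",
    "seasonal_adjust",
    "detrend_linear",
    "adf_check",
    "symbolize_changes",
    "symbolize_events",
]


@dataclass
class SymbolicSeries:
    """A binary-symbolized series with its provenance."""

    symbols: np.ndarray
    rule: str  # "change" or "event"
    source_label: str = ""

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.uint8)
        if self.rule not in ("change", "event"):
            raise ValueError(f"unknown symbolization rule {self.rule!r}")
        if self.symbols.ndim != 1 or not np.all(np.isin(self.symbols, (0, 1))):
            raise ValueError("symbols must be a 1-d binary vector")

    def __len__(self) -> int:
        return len(self.symbols)


def seasonal_adjust(series: np.ndarray, period: int = 12) -> np.ndarray:
    """Remove an additive periodic component (classical decomposition).

    The trend is a centered moving average; the seasonal factors are the
    within-period means of the detrended series, normalized to sum to zero
    over one period, so the adjustment is mean-preserving. Requires at least
    two full periods.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if len(x) < 2 * period:
        raise ValueError(f"need at least {2 * period} observations (two periods)")
    dec = seasonal_decompose(x, period=period, model="additive", two_sided=True)
    return x - dec.seasonal


def detrend_linear(series: np.ndarray) -> np.ndarray:
    """Residuals after removing the least-squares line on the time index."""
    x = np.asarray(series, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations to detrend")
    t = np.arange(len(x), dtype=float)
    coef = np.polyfit(t, x, 1)
    return x - np.polyval(coef, t)


def adf_check(series: np.ndarray, max_lag: Optional[int] = None) -> dict:
    """Augmented Dickey-Fuller unit-root check (constant, AIC lag choice).

    Returns the test statistic, the MacKinnon p-value, the lag used, and
    ``reject_unit_root`` at the 5% critical value. A constant series is a
    degenerate input and raises.
    """
    x = np.asarray(series, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant series: unit-root test undefined")
    if max_lag is not None and len(x) <= max_lag + 10:
        raise ValueError("series too short for the requested max_lag")
    stat, pvalue, usedlag, nobs, crit, _ = adfuller(
        x, maxlag=max_lag, regression="c", autolag="AIC"
    )
    return {
        "statistic": float(stat),
        "pvalue": float(pvalue),
        "used_lag": int(usedlag),
        "reject_unit_root": bool(stat < crit["5%"]),
    }


def symbolize_changes(series: np.ndarray, label: str = "") -> SymbolicSeries:
    """1 where the next value is strictly greater, else 0; length M-1."""
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 observations to symbolize changes")
    return SymbolicSeries(
        symbols=(x[1:] > x[:-1]).astype(np.uint8), rule="change", source_label=label
    )


def symbolize_events(counts: np.ndarray, label: str = "") -> SymbolicSeries:
    """1 where at least one event occurred that month; length preserved."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0) or np.any(c != np.round(c)):
        raise ValueError("event counts must be nonnegative integers")
    return SymbolicSeries(
        symbols=(c >= 1).astype(np.uint8), rule="event", source_label=label
    )
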