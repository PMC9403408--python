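"""Anchored monthly prediction of ownership and fit evaluation.

Prediction iterates the calibrated model month by month with the noise set
to zero. The 12 months of the virtual burn-in year are filled with the first
survey year's October values. To keep a long horizon from drifting, each
October's 12-month lag is taken from the previous October's *survey* values
(the anchor); every other month uses the model's own output from 12 months
earlier. A missing survey anchor falls back to the model's value with a
logged warning.

The national series is produced the same way the state series are: the
model is iterated on nationally aggregated proxies with a single spatial
unit (all spatial terms vanish), not by averaging state outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .model import ModelParameters, monthly_rhs, solve_contemporaneous, check_rho
from .panel import StatePanel, register_result
from .weights import WeightMatrixSequence, null_W

__all__ = [
    "PredictionResult",
    "FitEvaluation",
    "predict_monthly",
    "national_aggregate",
    "evaluate_fit",
]

logger = logging.getLogger(__name__)


@register_result
@dataclass
class PredictionResult:
    """Monthly state-level predictions plus the national series."""

    monthly: np.ndarray  # (n, M) ownership fractions (unclipped)
    national: Optional[np.ndarray] = None  # (M,)
    anchors_used: list = field(default_factory=list)  # [(year, source), ...]
    unit_ids: list = field(default_factory=list)
    months: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.monthly = np.asarray(self.monthly, dtype=float)
        if self.national is not None:
            self.national = np.asarray(self.national, dtype=float)

    def clipped(self) -> np.ndarray:
        """Monthly predictions clipped to [0, 1] — display only; the linear
        model is estimated and evaluated unclipped."""
        return np.clip(self.monthly, 0.0, 1.0)


def _iterate_anchored(
    params: ModelParameters,
    Wseq: WeightMatrixSequence,
    X1: np.ndarray,
    X2: np.ndarray,
    survey_Y: np.ndarray,
    high_mask: np.ndarray,
    years: list[int],
    Y_init: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, list]:
    n, M = X1.shape
    T = M // 12
    if Y_init is None:
        y0 = survey_Y[:, 0]
        if np.isnan(y0).any():
            raise ValueError(
                "first survey year has missing anchors; cannot seed burn-in"
            )
        Y_init = np.tile(y0[:, None], (1, 12))
    else:
        Y_init = np.asarray(Y_init, dtype=float)
        if Y_init.shape != (n, 12):
            raise ValueError("Y_init must have shape (n, 12)")
    noiseless = ModelParameters(
        **{f: getattr(params, f) for f in params.names() if f != "sigma2"},
        sigma2=0.0,
    )
    check_rho(noiseless.rho, Wseq.eigenvalues())
    Y = np.empty((n, M))
    anchors: list = []
    for m in range(M):
        t = m // 12
        W = Wseq.matrices[t]
        month_of_year = m % 12  # 9 == October
        if m < 12:
            y_lag = Y_init[:, m]  # virtual burn-in year
            if month_of_year == 9:
                anchors.append((years[t], "burnin"))
        elif month_of_year == 9:
            prev = survey_Y[:, t - 1]
            if np.isnan(prev).any():
                bad = np.isnan(prev)
                logger.warning(
                    "missing survey anchor(s) for year %s; falling back to "
                    "model output for %d unit(s)",
                    years[t - 1],
                    int(bad.sum()),
                )
                y_lag = np.where(bad, Y[:, m - 12], prev)
                anchors.append((years[t], "model"))
            else:
                y_lag = prev
                anchors.append((years[t], "survey"))
        else:
            y_lag = Y[:, m - 12]
        x1 = X1[:, m - 1] if m >= 1 else X1[:, 0]
        x2 = X2[:, m - 1] if m >= 1 else X2[:, 0]
        W_x = Wseq.matrices[max(m - 1, 0) // 12]
        rhs = monthly_rhs(noiseless, W, y_lag, x1, x2, t, high_mask, W_x=W_x)
        Y[:, m] = solve_contemporaneous(noiseless, W, rhs)
    return Y, anchors


def predict_monthly(
    params: ModelParameters,
    panel: StatePanel,
    Wseq: WeightMatrixSequence,
    include_national: bool = True,
    suicide_counts: Optional[np.ndarray] = None,
    Y_init: Optional[np.ndarray] = None,
) -> PredictionResult:
    """October-anchored monthly prediction for every state (sigma2 = 0).

    ``Y_init`` optionally overrides the virtual burn-in year; by default the
    first survey year's October values fill all 12 burn-in months.
    """
    monthly, anchors = _iterate_anchored(
        params,
        Wseq,
        panel.X1,
        panel.X2,
        panel.survey_Y,
        panel.high_mask(),
        list(panel.years),
        Y_init=Y_init,
    )
    national = None
    if include_national:
        national = national_aggregate(
            panel, params, Wseq, suicide_counts=suicide_counts
        )
    return PredictionResult(
        monthly=monthly,
        national=national,
        anchors_used=anchors,
        unit_ids=list(panel.unit_ids),
        months=list(panel.months),
    )


def national_aggregate(
    panel: StatePanel,
    params: ModelParameters,
    Wseq: WeightMatrixSequence,
    suicide_counts: Optional[np.ndarray] = None,
) -> np.ndarray:
    """National ownership series from nationally aggregated proxies.

    National background checks per capita sum the reconstructed monthly
    check counts (rate x population) over states and divide by the total
    population. The national firearm-suicide fraction divides total firearm
    suicides by total suicides when per-state monthly ``suicide_counts``
    (n, M) are supplied; otherwise it falls back to the population-weighted
    mean of the state fractions (an approximation, since the panel stores
    fractions, not counts). The model is then iterated on these aggregates
    as a single unit with no spatial interaction, anchored on the
    population-weighted national survey values.
    """
    n, M, T = panel.n, panel.M, panel.T
    pop_m = panel.populations[:, np.repeat(np.arange(T), 12)]  # (n, M)
    total_pop = pop_m.sum(axis=0)
    x1_nat = (panel.X1 * pop_m).sum(axis=0) / total_pop
    if suicide_counts is not None:
        counts = np.asarray(suicide_counts, dtype=float)
        if counts.shape != (n, M):
            raise ValueError("suicide_counts must have shape (n, M)")
        totals = counts.sum(axis=0)
        if np.any(totals == 0):
            m = int(np.flatnonzero(totals == 0)[0])
            raise ValueError(
                f"zero total suicides in month {panel.months[m]}: national "
                "fraction undefined"
            )
        x2_nat = (panel.X2 * counts).sum(axis=0) / totals
    else:
        x2_nat = (panel.X2 * pop_m).sum(axis=0) / total_pop

    pop_t = panel.populations
    with np.errstate(invalid="ignore"):
        wsum = np.where(np.isfinite(panel.survey_Y), pop_t, 0.0)
        num = np.nansum(panel.survey_Y * pop_t, axis=0)
        survey_nat = num / wsum.sum(axis=0)

    nat_params = ModelParameters(
        **{
            f: getattr(params, f)
            for f in params.names()
            if f not in ("rho", "eta", "psi1", "psi2", "sigma2")
        },
        rho=0.0,
        eta=0.0,
        psi1=0.0,
        psi2=0.0,
        sigma2=0.0,
    )
    Y, _ = _iterate_anchored(
        nat_params,
        null_W(1, T),
        x1_nat[None, :],
        x2_nat[None, :],
        survey_nat[None, :],
        np.array([True]),
        list(panel.years),
    )
    return Y[0]


@register_result
@dataclass
class FitEvaluation:
    """October squared-error summary of a prediction against the survey."""

    sse: float
    mse: float
    n_compared: int
    per_unit: Optional[dict] = None  # unit -> {sse, mse, n}

    def per_unit_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_unit).T


def evaluate_fit(
    pred: PredictionResult,
    survey_Y: np.ndarray,
    panel: Optional[StatePanel] = None,
) -> FitEvaluation:
    """Squared October differences: SSE (sum) and MSE (SSE / #Octobers).

    ``survey_Y`` is (n, T); predictions are compared at each year's October
    column. NaN survey cells are skipped; at least one overlapping October
    is required.
    """
    survey_Y = np.asarray(survey_Y, dtype=float)
    monthly = pred.monthly
    n, M = monthly.shape
    T = M // 12
    if survey_Y.shape != (n, T):
        raise ValueError(f"survey_Y must have shape ({n}, {T})")
    october = monthly[:, 9::12]
    valid = np.isfinite(survey_Y)
    n_cmp = int(valid.sum())
    if n_cmp == 0:
        raise ValueError("no overlapping October observations to compare")
    sq = np.where(valid, (october - survey_Y) ** 2, 0.0)
    sse = float(sq.sum())
    per_unit = None
    if panel is not None:
        per_unit = {}
        for i, u in enumerate(panel.unit_ids):
            k = int(valid[i].sum())
            s = float(sq[i].sum())
            per_unit[u] = {"sse": s, "mse": s / k if k else np.nan, "n": k}
    return FitEvaluation(sse=sse, mse=sse / n_cmp, n_compared=n_cmp, per_unit=per_unit)
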