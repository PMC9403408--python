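"""Discrete transfer-entropy engine with a stratified local permutation test.

All quantities are plug-in estimates over binary symbol sequences under a
first-order embedding: the joint distribution of (X_{t+1}, X_t, Y_{t-lag},
Z_{t-lag}) is estimated by relative frequencies over the 16 joint states,
and the conditional transfer entropy from source Y to target X given
conditioner Z is

    TE_{Y->X|Z} = H(X_{t+1} | X_t, Z_t) - H(X_{t+1} | X_t, Y_t, Z_t),

in bits. No bias correction is applied to the estimator; finite-sample bias
is absorbed by the permutation null instead. Significance uses a *local*
permutation scheme: within each stratum defined by the realized pair
(X_t, Z_t) — the four cells (0,0), (0,1), (1,0), (1,1) — the source symbols
are shuffled among the time points of that stratum only, which preserves the
conditional structure of the null. The p-value is the right-tail fraction
(1 + #{surrogate >= observed}) / (1 + n_permutations); ties count toward the
surrogate tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .panel import register_result
from .preprocess import (
    SymbolicSeries,
    detrend_linear,
    seasonal_adjust,
    symbolize_changes,
    symbolize_events,
)

__all__ = [
    "JointDistribution",
    "TEResult",
    "shannon_entropy",
    "conditional_te",
    "local_permutation_test",
    "triad_analysis",
    "TriadResult",
]

MIN_LENGTH = 20


@dataclass
class JointDistribution:
    """Plug-in joint distribution over tuples of binary symbols."""

    probabilities: np.ndarray  # shape (2,) * k
    variable_labels: tuple = ()

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be nonnegative and sum to 1")
        self.probabilities = p

    @classmethod
    def from_symbols(cls, *arrays: np.ndarray, labels: tuple = ()) -> "JointDistribution":
        arrs = [np.asarray(a, dtype=np.int64) for a in arrays]
        L = len(arrs[0])
        if any(len(a) != L for a in arrs):
            raise ValueError("all symbol arrays must share a length")
        code = np.zeros(L, dtype=np.int64)
        for a in arrs:
            code = code * 2 + a
        counts = np.bincount(code, minlength=2 ** len(arrs)).astype(float)
        return cls((counts / counts.sum()).reshape((2,) * len(arrs)), labels)

    def marginal(self, axes: tuple) -> "JointDistribution":
        keep = tuple(sorted(axes))
        drop = tuple(i for i in range(self.probabilities.ndim) if i not in keep)
        return JointDistribution(
            self.probabilities.sum(axis=drop),
            tuple(self.variable_labels[i] for i in keep) if self.variable_labels else (),
        )

    def entropy(self) -> float:
        return shannon_entropy(self.probabilities)


def shannon_entropy(probabilities: np.ndarray) -> float:
    """Shannon entropy in bits, with the 0*log(0) = 0 convention."""
    p = np.asarray(probabilities, dtype=float).ravel()
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


@register_result
@dataclass
class TEResult:
    """Conditional transfer entropy with (optionally) its permutation test."""

    te_bits: float
    p_value: Optional[float] = None
    n_permutations: int = 0
    source: str = ""
    target: str = ""
    conditioner: str = ""
    lag: int = 0

    @property
    def significant(self) -> Optional[bool]:
        """Observed TE beyond the surrogate distribution's 95th percentile."""
        return None if self.p_value is None else bool(self.p_value < 0.05)


def _as_symbols(s: Union[SymbolicSeries, np.ndarray]) -> np.ndarray:
    a = s.symbols if isinstance(s, SymbolicSeries) else np.asarray(s)
    a = np.asarray(a)
    if a.ndim != 1 or not np.all(np.isin(a, (0, 1))):
        raise ValueError("symbol series must be 1-d binary")
    return a.astype(np.int64)


def _embed(target, source, conditioner, lag: int):
    """Aligned (X_{t+1}, X_t, Y_{t-lag}, Z_{t-lag}) symbol columns."""
    x = _as_symbols(target)
    y = _as_symbols(source)
    z = _as_symbols(conditioner)
    if not len(x) == len(y) == len(z):
        raise ValueError("target, source and conditioner must share a length")
    if lag < 0:
        raise ValueError("lag must be nonnegative")
    L = len(x)
    if L - 1 - lag < MIN_LENGTH:
        raise ValueError(
            f"need at least {MIN_LENGTH} aligned transitions (have {L - 1 - lag})"
        )
    t = np.arange(lag, L - 1)
    return x[t + 1], x[t], y[t - lag], z[t - lag]


def _te_from_counts(counts: np.ndarray) -> np.ndarray:
    """TE for count tensors with axes (..., x_next, x_now, y, z).

    Vectorized over leading axes so permutation surrogates evaluate in bulk.
    """
    c = counts.reshape(counts.shape[:-1] + (2, 2, 2, 2))
    total = c.sum(axis=(-4, -3, -2, -1), keepdims=True)
    p = c / total

    def _H(q: np.ndarray, axes) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(q > 0, q * np.log2(np.where(q > 0, q, 1.0)), 0.0)
        return -term.sum(axis=axes)

    # H(x_next | x_now, z) = H(x_next, x_now, z) - H(x_now, z)
    p_xxz = p.sum(axis=-2)
    h1 = _H(p_xxz, (-3, -2, -1)) - _H(p_xxz.sum(axis=-3), (-2, -1))
    # H(x_next | x_now, y, z) = H(all) - H(x_now, y, z)
    h2 = _H(p, (-4, -3, -2, -1)) - _H(p.sum(axis=-4), (-3, -2, -1))
    return h1 - h2


def conditional_te(
    target,
    source,
    conditioner,
    lag: int = 0,
    labels: tuple[str, str, str] = ("", "", ""),
) -> TEResult:
    """Plug-in conditional transfer entropy source -> target | conditioner.

    ``lag`` shifts the source and conditioner jointly back by that many
    steps (0 is the contemporaneous-history analysis; 1..11 probe delayed
    influence).
    """
    xn, xp, ys, zs = _embed(target, source, conditioner, lag)
    code = ((xn * 2 + xp) * 2 + ys) * 2 + zs
    counts = np.bincount(code, minlength=16).astype(float)
    te = float(_te_from_counts(counts))
    tgt, src, cond = labels
    return TEResult(
        te_bits=te, source=src, target=tgt, conditioner=cond, lag=lag
    )


def local_permutation_test(
    target,
    source,
    conditioner,
    lag: int = 0,
    n_permutations: int = 50_000,
    seed: Optional[int] = None,
    labels: tuple[str, str, str] = ("", "", ""),
    batch_size: int = 5_000,
) -> TEResult:
    """Stratified surrogate test of conditional transfer entropy.

    Source symbols are shuffled only within the four strata defined by the
    realized (X_t, Z_t) pair, so each stratum's multiset of source symbols —
    and hence the empirical conditioning structure — is preserved in every
    surrogate. An empty stratum simply has nothing to shuffle.
    """
    xn, xp, ys, zs = _embed(target, source, conditioner, lag)
    L = len(xn)
    base_code = ((xn * 2 + xp) * 2) * 2 + zs  # y contribution added per surrogate
    observed = float(
        _te_from_counts(
            np.bincount(base_code + 2 * ys, minlength=16).astype(float)
        )
    )

    strata = xp * 2 + zs
    stratum_idx = [np.flatnonzero(strata == s) for s in range(4)]
    rng = np.random.default_rng(seed)

    n_ge = 0
    done = 0
    while done < n_permutations:
        B = min(batch_size, n_permutations - done)
        y_surr = np.broadcast_to(ys, (B, L)).copy()
        for idx in stratum_idx:
            if len(idx) < 2:
                continue  # empty or singleton stratum: left untouched
            order = np.argsort(rng.random((B, len(idx))), axis=1)
            y_surr[:, idx] = ys[idx][order]
        codes = base_code[None, :] + 2 * y_surr
        flat = (np.arange(B)[:, None] * 16 + codes).ravel()
        counts = (
            np.bincount(flat, minlength=B * 16).reshape(B, 16).astype(float)
        )
        te_surr = _te_from_counts(counts)
        n_ge += int(np.sum(te_surr >= observed - 1e-12))
        done += B

    p = (1 + n_ge) / (1 + n_permutations)
    tgt, src, cond = labels
    return TEResult(
        te_bits=observed,
        p_value=float(p),
        n_permutations=n_permutations,
        source=src,
        target=tgt,
        conditioner=cond,
        lag=lag,
    )


DEFAULT_PLAN = {"seasonal_adjust": True, "detrend": True, "rule": "change"}


@register_result
@dataclass
class TriadResult:
    """All six directed, conditioned links among three series."""

    links: list = field(default_factory=list)  # list of TEResult

    def table(self) -> pd.DataFrame:
        """Source-by-target table of 'te (p)' strings, six populated cells."""
        names = sorted({r.source for r in self.links} | {r.target for r in self.links})
        df = pd.DataFrame("-", index=names, columns=names)
        for r in self.links:
            df.loc[r.source, r.target] = f"{r.te_bits:.4f} ({r.p_value:.4f})"
        df.index.name = "source"
        return df


def _prepare(values: np.ndarray, plan: dict, label: str) -> SymbolicSeries:
    plan = {**DEFAULT_PLAN, **plan}
    if plan["rule"] == "event":
        return symbolize_events(values, label)
    x = np.asarray(values, dtype=float)
    if plan.get("seasonal_adjust", False):
        x = seasonal_adjust(x)
    if plan.get("detrend", False):
        x = detrend_linear(x)
    return symbolize_changes(x, label)


def triad_analysis(
    series_map: dict,
    plans: Optional[dict] = None,
    n_permutations: int = 50_000,
    seed: Optional[int] = None,
    lag: int = 0,
) -> TriadResult:
    """Preprocess, symbolize, and test all six ordered pairs of a triad.

    ``series_map`` maps three labels to value arrays (or AnalysisSeries);
    ``plans`` maps labels to per-series preprocessing plans (keys
    ``seasonal_adjust``, ``detrend``, ``rule``). Each link is conditioned on
    the remaining third variable. Symbolized series are truncated to their
    common length (change-rule series are one shorter than their input, so
    event series lose their final element).
    """
    if len(series_map) != 3:
        raise ValueError("triad_analysis requires exactly three labeled series")
    plans = plans or {}
    symbols: dict[str, np.ndarray] = {}
    for label, series in series_map.items():
        values = getattr(series, "values", series)
        symbols[label] = _prepare(values, plans.get(label, {}), label).symbols
    common = min(len(s) for s in symbols.values())
    symbols = {k: v[:common] for k, v in symbols.items()}

    names = list(symbols)
    rng = np.random.default_rng(seed)
    links = []
    for src in names:
        for tgt in names:
            if src == tgt:
                continue
            cond = next(x for x in names if x not in (src, tgt))
            links.append(
                local_permutation_test(
                    symbols[tgt],
                    symbols[src],
                    symbols[cond],
                    lag=lag,
                    n_permutations=n_permutations,
                    seed=int(rng.integers(2**31 - 1)),
                    labels=(tgt, src, cond),
                )
            )
    return TriadResult(links=links)
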