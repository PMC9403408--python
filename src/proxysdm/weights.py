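"""Time-varying spatial weight matrices.

The default interaction matrix follows a gravity-like rule: the influence of
unit *j* on unit *i* grows with *j*'s population and shrinks with the
great-circle distance between their centroids,

    W[i, j] = p[j] / (K[i] * D[i, j]),   K[i] = sum_{j != i} p[j] / D[i, j],

with zero diagonal, so every row sums to one (row-stochastic). Populations
are yearly, hence one matrix per year, constant across the 12 months of that
year. An all-zero "null" matrix switches off spatial interaction entirely and
reduces the model to an ordinary (non-spatial) regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "EARTH_RADIUS_KM",
    "WeightMatrixSequence",
    "pairwise_distance",
    "build_population_distance_W",
    "build_custom_W",
    "null_W",
]

EARTH_RADIUS_KM = 6371.0

_ROW_SUM_TOL = 1e-12


@dataclass
class WeightMatrixSequence:
    """One row-stochastic n x n matrix per year (or the all-zero null)."""

    matrices: np.ndarray  # (T, n, n)
    year_index: list[int]
    is_null: bool = False
    _eigvals: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must have shape (T, n, n)")
        if len(self.year_index) != self.matrices.shape[0]:
            raise ValueError("year_index length must match number of matrices")
        diag = np.diagonal(self.matrices, axis1=1, axis2=2)
        if np.any(diag != 0):
            raise ValueError("weight matrices must have zero diagonal")
        if np.any(self.matrices < 0):
            raise ValueError("weight matrix entries must be nonnegative")
        if not self.is_null:
            rows = self.matrices.sum(axis=2)
            if np.any(np.abs(rows - 1.0) > _ROW_SUM_TOL):
                raise ValueError("weight matrix rows must sum to 1")

    @property
    def T(self) -> int:
        return self.matrices.shape[0]

    @property
    def n(self) -> int:
        return self.matrices.shape[1]

    def for_year(self, year: int) -> np.ndarray:
        return self.matrices[self.year_index.index(year)]

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues of the block-diagonal stacked matrix (union of the
        per-year spectra), used for the spatial parameter's feasible interval
        and the exact log-determinant."""
        if self._eigvals is None:
            self._eigvals = np.concatenate(
                [np.linalg.eigvals(W) for W in self.matrices]
            )
        return self._eigvals


def pairwise_distance(centroids: np.ndarray) -> np.ndarray:
    """Great-circle (haversine) distances in km between centroid pairs.

    Parameters
    ----------
    centroids : ndarray, shape (n, 2)
        (latitude, longitude) in degrees.

    Returns
    -------
    ndarray, shape (n, n)
        Symmetric, zero diagonal. Raises if two distinct units share a
        centroid (the inverse-distance weight rule would divide by zero).
    """
    c = np.asarray(centroids, dtype=float)
    if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 2:
        raise ValueError("centroids must have shape (n >= 2, 2)")
    lat, lon = np.radians(c[:, 0]), np.radians(c[:, 1])
    if np.any(np.abs(c[:, 0]) > 90) or np.any(np.abs(c[:, 1]) > 180):
        raise ValueError("latitudes must lie in [-90, 90], longitudes in [-180, 180]")
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * (
        np.sin(dlon / 2) ** 2
    )
    D = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    off = ~np.eye(len(c), dtype=bool)
    if np.any(D[off] == 0):
        i, j = np.argwhere((D == 0) & off)[0]
        raise ValueError(
            f"units {i} and {j} share a centroid; distances must be positive"
        )
    return D


def _normalize_rows(raw: np.ndarray) -> np.ndarray:
    np.fill_diagonal(raw, 0.0)
    K = raw.sum(axis=1, keepdims=True)
    if np.any(K <= 0):
        raise ValueError("a row of raw weights sums to zero; cannot normalize")
    return raw / K


def build_population_distance_W(
    populations: np.ndarray,
    distances: np.ndarray,
    year_index: list[int] | None = None,
) -> WeightMatrixSequence:
    """Population-over-distance weights, row-normalized, one matrix per year.

    ``populations`` is (n, T); ``distances`` (n, n) with positive
    off-diagonal. The same yearly population applies to all 12 months of
    that year.
    """
    P = np.asarray(populations, dtype=float)
    D = np.asarray(distances, dtype=float)
    if P.ndim != 2:
        raise ValueError("populations must be an (n, T) matrix")
    n, T = P.shape
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match populations")
    if np.any(P <= 0):
        raise ValueError("populations must be strictly positive")
    off = ~np.eye(n, dtype=bool)
    if np.any(D[off] <= 0):
        raise ValueError("off-diagonal distances must be strictly positive")
    Dsafe = D.copy()
    np.fill_diagonal(Dsafe, 1.0)  # diagonal never used; avoid 0/0
    mats = np.empty((T, n, n))
    for t in range(T):
        mats[t] = _normalize_rows(P[None, :, t] / Dsafe)
    years = list(year_index) if year_index is not None else list(range(T))
    return WeightMatrixSequence(mats, years)


def build_custom_W(
    raw_builder: Callable[..., np.ndarray],
    populations: np.ndarray,
    distances: np.ndarray,
    year_index: list[int] | None = None,
    **extras,
) -> WeightMatrixSequence:
    """Plug-in builder: user function -> raw yearly weights -> row-normalized.

    ``raw_builder(populations_year, distances, **extras)`` must return an
    (n, n) array of nonnegative raw weights for one year; the diagonal is
    zeroed and rows are normalized here.
    """
    P = np.asarray(populations, dtype=float)
    n, T = P.shape
    mats = np.empty((T, n, n))
    for t in range(T):
        raw = np.array(raw_builder(P[:, t], distances, **extras), dtype=float)
        if raw.shape != (n, n):
            raise ValueError("raw_builder must return an (n, n) array")
        mats[t] = _normalize_rows(raw)
    years = list(year_index) if year_index is not None else list(range(T))
    return WeightMatrixSequence(mats, years)


def null_W(n: int, T: int, year_index: list[int] | None = None) -> WeightMatrixSequence:
    """All-zero weight matrices: the no-spatial-interaction null model."""
    if n < 1 or T < 1:
        raise ValueError("n and T must be >= 1")
    years = list(year_index) if year_index is not None else list(range(T))
    return WeightMatrixSequence(np.zeros((T, n, n)), years, is_null=True)
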