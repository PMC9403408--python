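"""Panel containers and I/O for state-level proxy and survey data.

The central container is :class:`StatePanel`: monthly proxy series (background
checks per capita and the fraction of suicides committed with firearms),
annual October survey anchors of firearm ownership, yearly populations and
state centroid coordinates, for ``n`` spatial units over ``T`` years.

Input files are long-format UTF-8 CSV with a header row:

* proxies: ``unit,year,month,variable,value`` with ``variable`` in
  ``{x1, x2}`` (x1 = background checks per capita, x2 = fraction of
  suicides with firearms);
* survey: ``unit,year,value,respondents`` (October ownership fraction);
* populations: ``unit,year,population``;
* centroids: ``unit,lat,lon`` (degrees).

Missing survey cells are stored as NaN and flagged, never imputed here;
downstream stages decide how to treat them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PanelValidationError",
    "StatePanel",
    "AnalysisSeries",
    "read_panel",
    "classify_response",
    "write_results",
    "read_results",
]

SCHEMA_VERSION = 1

PROXY_VARIABLES = ("x1", "x2")


class PanelValidationError(ValueError):
    """Raised when panel inputs violate a structural invariant."""


@dataclass
class StatePanel:
    """Aligned monthly proxies, annual survey anchors, populations, centroids.

    Attributes
    ----------
    unit_ids : list of str
        Ordered labels of the ``n`` spatial units.
    years : list of int
        The ``T`` survey years, consecutive.
    months : list of (int, int)
        The ``M`` (year, month) pairs of the proxy series, consecutive.
    X1, X2 : ndarray, shape (n, M)
        Background checks per capita (checks/person/month, nonnegative) and
        fraction of suicides with firearms (in [0, 1]).
    survey_Y : ndarray, shape (n, T)
        October ownership fractions; NaN marks a missing cell.
    populations : ndarray, shape (n, T)
        Yearly populations (persons, positive).
    centroids : ndarray, shape (n, 2)
        (latitude, longitude) in degrees.
    response_class : ndarray of str, shape (n,)
        'H' (high survey response) or 'L' (low).
    """

    unit_ids: list[str]
    years: list[int]
    months: list[tuple[int, int]]
    X1: np.ndarray
    X2: np.ndarray
    survey_Y: np.ndarray
    populations: np.ndarray
    centroids: np.ndarray
    response_class: np.ndarray

    def __post_init__(self) -> None:
        self.X1 = np.asarray(self.X1, dtype=float)
        self.X2 = np.asarray(self.X2, dtype=float)
        self.survey_Y = np.asarray(self.survey_Y, dtype=float)
        self.populations = np.asarray(self.populations, dtype=float)
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.response_class = np.asarray(self.response_class, dtype="U1")
        n, M, T = self.n, self.M, self.T
        for name, arr, shape in [
            ("X1", self.X1, (n, M)),
            ("X2", self.X2, (n, M)),
            ("survey_Y", self.survey_Y, (n, T)),
            ("populations", self.populations, (n, T)),
            ("centroids", self.centroids, (n, 2)),
            ("response_class", self.response_class, (n,)),
        ]:
            if arr.shape != shape:
                raise PanelValidationError(
                    f"{name} has shape {arr.shape}, expected {shape}"
                )
        self._check_consecutive_months()

    # -- size properties ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.unit_ids)

    @property
    def M(self) -> int:
        return len(self.months)

    @property
    def T(self) -> int:
        return len(self.years)

    def high_mask(self) -> np.ndarray:
        return self.response_class == "H"

    def low_mask(self) -> np.ndarray:
        return self.response_class == "L"

    def month_index(self, year: int, month: int) -> int:
        try:
            return self.months.index((year, month))
        except ValueError:
            raise KeyError(f"month ({year}, {month}) not in panel") from None

    def _check_consecutive_months(self) -> None:
        for (y0, m0), (y1, m1) in zip(self.months, self.months[1:]):
            expected = (y0, m0 + 1) if m0 < 12 else (y0 + 1, 1)
            if (y1, m1) != expected:
                raise PanelValidationError(
                    f"months not consecutive: ({y0},{m0}) followed by ({y1},{m1})"
                )
        for y0, y1 in zip(self.years, self.years[1:]):
            if y1 != y0 + 1:
                raise PanelValidationError(
                    f"survey years not consecutive: {y0} followed by {y1}"
                )

    def validate(self, strict_fractions: bool = True) -> None:
        """Enforce value-range invariants.

        ``strict_fractions`` checks X2 and survey_Y against [0, 1]; synthetic
        anchors produced by the (unclipped) linear model may legitimately sit
        outside the unit interval, so range checks are opt-out.
        """
        if not np.all(np.isfinite(self.X1)) or not np.all(np.isfinite(self.X2)):
            raise PanelValidationError("proxy series contain non-finite values")
        if np.any(self.X1 < 0):
            raise PanelValidationError("X1 (background checks per capita) negative")
        if np.any(self.populations <= 0):
            raise PanelValidationError("populations must be strictly positive")
        if strict_fractions:
            if np.any((self.X2 < 0) | (self.X2 > 1)):
                raise PanelValidationError("X2 fraction out of [0,1]")
            sv = self.survey_Y[np.isfinite(self.survey_Y)]
            if np.any((sv < 0) | (sv > 1)):
                raise PanelValidationError("survey fraction out of [0,1]")
        if not set(self.response_class) <= {"H", "L"}:
            raise PanelValidationError("response_class labels must be 'H' or 'L'")

    def reorder_units(self, order: np.ndarray) -> "StatePanel":
        """Return a new panel with units permuted by ``order``."""
        order = np.asarray(order)
        return StatePanel(
            unit_ids=[self.unit_ids[i] for i in order],
            years=list(self.years),
            months=list(self.months),
            X1=self.X1[order],
            X2=self.X2[order],
            survey_Y=self.survey_Y[order],
            populations=self.populations[order],
            centroids=self.centroids[order],
            response_class=self.response_class[order],
        )


@dataclass
class AnalysisSeries:
    """A univariate monthly series entering the causal analysis."""

    label: str
    values: np.ndarray
    kind: str = "continuous"  # or "count"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("continuous", "count"):
            raise ValueError(f"unknown series kind {self.kind!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"series {self.label!r} contains non-finite values")
        if self.kind == "count":
            if np.any(self.values < 0) or np.any(self.values != np.round(self.values)):
                raise ValueError(
                    f"count series {self.label!r} must hold nonnegative integers"
                )


# ---------------------------------------------------------------------------
# readers


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise PanelValidationError(f"{what} table missing columns {missing}")


def read_panel(
    proxy_table: str | Path,
    survey_table: str | Path,
    population_table: str | Path,
    centroid_table: str | Path,
    respondent_threshold: int = 10,
) -> StatePanel:
    """Read and validate the four long-format CSV tables into a StatePanel.

    Units are sorted by label and months ascending, so the result is invariant
    to row order in the files. The H/L response split is derived from the
    survey table's ``respondents`` column via :func:`classify_response`.
    """
    proxies = pd.read_csv(proxy_table)
    survey = pd.read_csv(survey_table)
    pops = pd.read_csv(population_table)
    cents = pd.read_csv(centroid_table)

    _require_columns(proxies, ["unit", "year", "month", "variable", "value"], "proxy")
    _require_columns(survey, ["unit", "year", "value", "respondents"], "survey")
    _require_columns(pops, ["unit", "year", "population"], "population")
    _require_columns(cents, ["unit", "lat", "lon"], "centroid")

    units = sorted(cents["unit"].astype(str).unique())
    for what, df in [("proxy", proxies), ("survey", survey), ("population", pops)]:
        extra = set(df["unit"].astype(str)) - set(units)
        if extra:
            raise PanelValidationError(
                f"{what} table has unit(s) {sorted(extra)} absent from centroid table"
            )
        lacking = set(units) - set(df["unit"].astype(str))
        if lacking:
            raise PanelValidationError(
                f"unit(s) {sorted(lacking)} missing from {what} table"
            )

    months = sorted(
        {(int(y), int(m)) for y, m in zip(proxies["year"], proxies["month"])}
    )
    years = sorted(survey["year"].astype(int).unique())

    n, M, T = len(units), len(months), len(years)
    uidx = {u: i for i, u in enumerate(units)}
    midx = {ym: j for j, ym in enumerate(months)}
    yidx = {y: t for t, y in enumerate(years)}

    X = {v: np.full((n, M), np.nan) for v in PROXY_VARIABLES}
    for row in proxies.itertuples(index=False):
        var = str(row.variable)
        if var not in X:
            raise PanelValidationError(
                f"unknown proxy variable {var!r}; expected one of {PROXY_VARIABLES}"
            )
        X[var][uidx[str(row.unit)], midx[(int(row.year), int(row.month))]] = row.value
    for var, mat in X.items():
        if np.isnan(mat).any():
            i, j = np.argwhere(np.isnan(mat))[0]
            raise PanelValidationError(
                f"proxy {var} missing for unit {units[i]} month {months[j]}"
            )

    survey_Y = np.full((n, T), np.nan)
    respondents = np.zeros((n, T), dtype=int)
    for row in survey.itertuples(index=False):
        i, t = uidx[str(row.unit)], yidx[int(row.year)]
        v = float(row.value)
        if np.isfinite(v) and not 0.0 <= v <= 1.0:
            raise PanelValidationError(
                f"fraction out of [0,1]: survey value {v} for unit {row.unit}, "
                f"year {row.year}"
            )
        survey_Y[i, t] = v
        respondents[i, t] = int(row.respondents)

    populations = np.full((n, T), np.nan)
    for row in pops.itertuples(index=False):
        if int(row.year) in yidx:
            populations[uidx[str(row.unit)], yidx[int(row.year)]] = row.population
    if np.isnan(populations).any():
        i, t = np.argwhere(np.isnan(populations))[0]
        raise PanelValidationError(
            f"population missing for unit {units[i]} year {years[t]}"
        )

    centroids = np.zeros((n, 2))
    for row in cents.itertuples(index=False):
        centroids[uidx[str(row.unit)]] = (row.lat, row.lon)

    panel = StatePanel(
        unit_ids=units,
        years=years,
        months=months,
        X1=X["x1"],
        X2=X["x2"],
        survey_Y=survey_Y,
        populations=populations,
        centroids=centroids,
        response_class=classify_response(respondents, respondent_threshold),
    )
    panel.validate(strict_fractions=True)
    return panel


def classify_response(
    respondent_counts: np.ndarray, threshold: int = 10
) -> np.ndarray:
    """Partition units into high (H) and low (L) survey-response classes.

    A unit is H iff its respondent count strictly exceeds ``threshold`` in
    every year; otherwise (a count at or below the threshold in at least one
    year) it is L. The strict reading is deliberate: a count exactly equal to
    the threshold yields L.
    """
    counts = np.asarray(respondent_counts)
    if counts.ndim != 2:
        raise ValueError("respondent_counts must be an n x T matrix")
    if np.any(counts < 0):
        raise ValueError("respondent counts must be nonnegative")
    if np.any(counts != np.round(counts)):
        raise ValueError("respondent counts must be integers")
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    high = np.all(counts > threshold, axis=1)
    return np.where(high, "H", "L").astype("U1")


def write_panel_tables(
    panel: StatePanel,
    directory: str | Path,
    respondent_counts: np.ndarray | None = None,
) -> dict[str, Path]:
    """Write a panel back out as the four long-format CSV tables.

    The inverse of :func:`read_panel` (respondent counts default to a large
    constant when not supplied, preserving the H class on re-read for H
    units; pass the true counts to round-trip the H/L split).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n, M, T = panel.n, panel.M, panel.T
    if respondent_counts is None:
        respondent_counts = np.where(
            (panel.response_class == "H")[:, None], 1000, 1
        ) * np.ones((n, T), dtype=int)

    rows = []
    for i, u in enumerate(panel.unit_ids):
        for j, (y, m) in enumerate(panel.months):
            rows.append((u, y, m, "x1", panel.X1[i, j]))
            rows.append((u, y, m, "x2", panel.X2[i, j]))
    proxies = pd.DataFrame(rows, columns=["unit", "year", "month", "variable", "value"])

    survey = pd.DataFrame(
        [
            (u, y, panel.survey_Y[i, t], int(respondent_counts[i, t]))
            for i, u in enumerate(panel.unit_ids)
            for t, y in enumerate(panel.years)
        ],
        columns=["unit", "year", "value", "respondents"],
    )
    pops = pd.DataFrame(
        [
            (u, y, panel.populations[i, t])
            for i, u in enumerate(panel.unit_ids)
            for t, y in enumerate(panel.years)
        ],
        columns=["unit", "year", "population"],
    )
    cents = pd.DataFrame(
        [
            (u, panel.centroids[i, 0], panel.centroids[i, 1])
            for i, u in enumerate(panel.unit_ids)
        ],
        columns=["unit", "lat", "lon"],
    )
    paths = {}
    for name, df in [
        ("proxies", proxies),
        ("survey", survey),
        ("populations", pops),
        ("centroids", cents),
    ]:
        paths[name] = directory / f"{name}.csv"
        df.to_csv(paths[name], index=False)
    return paths


# ---------------------------------------------------------------------------
# result serialization
#
# Every result dataclass registered here round-trips through JSON with a
# top-level schema_version and type tag.

_RESULT_REGISTRY: dict[str, type] = {}


def register_result(cls: type) -> type:
    """Class decorator: make a dataclass (de)serializable by write/read_results."""
    _RESULT_REGISTRY[cls.__name__] = cls
    return cls


def _to_jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            "__dataclass__": type(obj).__name__,
            **{
                f.name: _to_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
            },
        }
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def _from_jsonable(obj):
    if isinstance(obj, dict) and "__dataclass__" in obj:
        name = obj["__dataclass__"]
        cls = _RESULT_REGISTRY.get(name)
        if cls is None:
            raise ValueError(f"unknown result type {name!r}")
        kwargs = {
            k: _from_jsonable(v) for k, v in obj.items() if k != "__dataclass__"
        }
        return cls(**kwargs)
    if isinstance(obj, dict):
        return {k: _from_jsonable(v) for k, v in obj.items()}
    return obj


def write_results(result, path: str | Path) -> None:
    """Serialize a registered result dataclass (or dict of them) to JSON."""
    payload = {"schema_version": SCHEMA_VERSION, "result": _to_jsonable(result)}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_results(path: str | Path):
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {payload.get('schema_version')}")
    return _from_jsonable(payload["result"])
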