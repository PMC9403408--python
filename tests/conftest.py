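"""Shared fixtures: small synthetic bundles and CSV fixture files."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import proxysdm as px


@pytest.fixture(scope="session")
def small_bundle():
    """A 10-unit, 6-year synthetic study bundle (binomial survey noise)."""
    cfg = px.ScenarioConfig(n_units=10, n_years=6, n_low_units=3, seed=42)
    return px.generate_scenario(cfg)


@pytest.fixture(scope="session")
def small_panel(small_bundle):
    return small_bundle["panel"]


def make_toy_panel(
    n=2,
    T=2,
    start_year=2000,
    x1=None,
    x2=None,
    survey=None,
    response=None,
):
    """Hand-buildable panel for exact bookkeeping tests."""
    M = 12 * T
    months = [(y, m) for y in range(start_year, start_year + T) for m in range(1, 13)]
    rng = np.random.default_rng(0)
    return px.StatePanel(
        unit_ids=[f"U{i}" for i in range(n)],
        years=list(range(start_year, start_year + T)),
        months=months,
        X1=np.full((n, M), 0.005) if x1 is None else x1,
        X2=np.full((n, M), 0.5) if x2 is None else x2,
        survey_Y=np.full((n, T), 0.3) if survey is None else survey,
        populations=np.tile(
            rng.uniform(1e6, 5e6, size=n)[:, None], (1, T)
        ),
        centroids=np.column_stack(
            [np.linspace(30, 45, n), np.linspace(-120, -80, n)]
        ),
        response_class=np.array(["H"] * n if response is None else response),
    )


@pytest.fixture
def toy_panel():
    return make_toy_panel()


@pytest.fixture
def panel_csvs(tmp_path, small_bundle):
    """The small bundle written out as its four CSV tables."""
    paths = px.panel.write_panel_tables(
        small_bundle["panel"], tmp_path, small_bundle["respondent_counts"]
    )
    return paths
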