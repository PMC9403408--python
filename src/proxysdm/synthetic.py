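"""Synthetic study inputs with the statistical structure the pipeline assumes.

``generate_scenario`` emulates the real sources end to end: monthly
background checks per capita with strong December-peaking seasonality, a
slowly trending firearm-suicide fraction, yearly populations, grid-placed
centroids, an H/L survey-response split with per-year respondent counts
(low-response units can have single-digit — even single-respondent —
years), monthly ownership simulated from the spatial Durbin model itself,
October survey anchors with binomial sampling noise, a Poisson
mass-shooting count series and a log-normal media-output series (optionally
coupled to the shootings). Everything is driven by one seed.

The default configuration mirrors the study scale: 48 units, 20 years
(240 months), model parameters at the magnitudes recovered on the real
panel (rho = 0.163, sigma2 = 0.031, proxy coefficients of order 18-70 per
background check and 0.3-1.6 on the suicide fraction), and proxy levels
(about 0.0066 checks/person/month, suicide fraction near 0.55) chosen so
the implied ownership fraction sits in a realistic 0.3-0.4 band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .model import ModelParameters, simulate_panel
from .panel import AnalysisSeries, StatePanel, classify_response
from .weights import build_population_distance_W, pairwise_distance

__all__ = ["ScenarioConfig", "default_true_params", "generate_scenario",
           "generate_coupled_triad"]


def default_true_params() -> ModelParameters:
    """Operating point at the magnitudes estimated on the real panel."""
    return ModelParameters(
        rho=0.163,
        tau=0.0034,
        eta=-0.0493,
        phi1_H=18.16,
        phi1_L=36.60,
        phi2_H=0.5285,
        phi2_L=0.2741,
        psi1=-70.25,
        psi2=1.599,
        gamma=0.0104,
        alpha_H=-0.6225,
        alpha_L=-0.5080,
        sigma2=0.031,
    )


@dataclass
class ScenarioConfig:
    """Knobs of the synthetic study. Defaults ARE the study conditions."""

    n_units: int = 48
    n_years: int = 20
    start_year: int = 2000
    true_params: ModelParameters = field(default_factory=default_true_params)
    x1_mean: float = 0.0066  # checks/person/month
    x1_seasonal_amplitude: float = 0.35  # relative, December peak
    x1_noise: float = 0.08  # relative lognormal scatter
    x2_mean: float = 0.55
    x2_trend_per_year: float = -0.002
    x2_noise: float = 0.012
    n_low_units: int = 10
    respondents_high: tuple[int, int] = (12, 60)
    respondents_low: tuple[int, int] = (1, 9)
    infinite_respondents: bool = False
    event_rate: float = 0.5  # shootings per month
    media_noise_scale: float = 0.5  # lognormal sigma
    media_coupling: float = 0.0  # added log-mean after an event month
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 2:
            raise ValueError("need at least 2 spatial units")
        if self.n_years < 3:
            raise ValueError("need at least 3 years")
        for name in ("x1_mean", "x1_seasonal_amplitude", "x1_noise", "x2_noise",
                     "event_rate", "media_noise_scale"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) < 0:
                raise ValueError(f"{name} must be finite and nonnegative")


def _grid_centroids(n: int) -> np.ndarray:
    """Deterministic grid over a continental-US-like bounding box."""
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    lat = np.linspace(30.0, 47.0, rows)
    lon = np.linspace(-120.0, -75.0, cols)
    pts = [(la, lo) for la in lat for lo in lon]
    return np.array(pts[:n])


def generate_scenario(config: ScenarioConfig) -> dict:
    """Generate a complete fake study bundle.

    Returns a dict with keys ``panel`` (StatePanel), ``true_ownership``
    ((n, M) simulated monthly ownership), ``series`` (mass shootings and
    media output AnalysisSeries), ``respondent_counts`` ((n, T)),
    ``true_params`` and ``weights``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, T = cfg.n_units, cfg.n_years
    M = 12 * T
    years = list(range(cfg.start_year, cfg.start_year + T))
    months = [(y, m) for y in years for m in range(1, 13)]
    unit_ids = [f"S{i:02d}" for i in range(n)]

    # geography and population
    centroids = _grid_centroids(n)
    base_pop = np.exp(rng.normal(14.5, 1.0, size=n))  # ~0.4M-10M persons
    growth = 1.0 + rng.uniform(0.0, 0.012, size=n)
    populations = base_pop[:, None] * growth[:, None] ** np.arange(T)[None, :]

    # survey response classes: least populated units respond least
    order = np.argsort(base_pop)
    low_units = order[: min(cfg.n_low_units, n - 1)]  # keep >= 1 high unit
    respondents = rng.integers(
        cfg.respondents_high[0], cfg.respondents_high[1] + 1, size=(n, T)
    )
    respondents[low_units] = rng.integers(
        cfg.respondents_low[0], cfg.respondents_low[1] + 1,
        size=(len(low_units), T),
    )
    response_class = classify_response(respondents, threshold=10)
    high_mask = response_class == "H"

    # proxies
    month_idx = np.arange(M)
    season = 1.0 + cfg.x1_seasonal_amplitude * np.cos(
        2 * np.pi * (month_idx % 12 - 11) / 12.0
    )  # December (index 11) peak
    unit_level = np.exp(rng.normal(0.0, 0.15, size=n))
    X1 = (
        cfg.x1_mean
        * unit_level[:, None]
        * season[None, :]
        * np.exp(rng.normal(0.0, cfg.x1_noise, size=(n, M)))
    )
    x2_base = cfg.x2_mean + rng.normal(0.0, 0.05, size=n)
    X2 = np.clip(
        x2_base[:, None]
        + cfg.x2_trend_per_year * (month_idx[None, :] / 12.0)
        + rng.normal(0.0, cfg.x2_noise, size=(n, M)),
        0.01,
        0.99,
    )

    weights = build_population_distance_W(
        populations, pairwise_distance(centroids), year_index=years
    )

    # ownership trajectory from the model itself
    y_start = np.clip(rng.normal(0.35, 0.05, size=n), 0.1, 0.6)
    Y_init = np.tile(y_start[:, None], (1, 12))
    sim_seed = int(rng.integers(2**31 - 1))
    Y, october = simulate_panel(
        cfg.true_params, weights, X1, X2, Y_init,
        seed=sim_seed, high_mask=high_mask,
    )

    # survey anchors: binomial sampling around the simulated October truth
    if cfg.infinite_respondents:
        survey_Y = october.copy()
    else:
        p = np.clip(october, 0.0, 1.0)
        survey_Y = rng.binomial(respondents, p) / respondents

    panel = StatePanel(
        unit_ids=unit_ids,
        years=years,
        months=months,
        X1=X1,
        X2=X2,
        survey_Y=survey_Y,
        populations=populations,
        centroids=centroids,
        response_class=response_class,
    )

    # event and media series for the causal stage
    shootings = rng.poisson(cfg.event_rate, size=M).astype(float)
    log_media = rng.normal(np.log(50.0), cfg.media_noise_scale, size=M)
    if cfg.media_coupling > 0:
        bumps = np.zeros(M)
        bumps[1:] = cfg.media_coupling * (shootings[:-1] > 0)
        log_media = log_media + bumps
    series = {
        "mass_shootings": AnalysisSeries("mass_shootings", shootings, kind="count"),
        "media_output": AnalysisSeries("media_output", np.exp(log_media)),
    }

    return {
        "panel": panel,
        "true_ownership": Y,
        "series": series,
        "respondent_counts": respondents,
        "true_params": replace(cfg.true_params),
        "weights": weights,
    }


def generate_coupled_triad(
    coupling: str,
    length: int,
    strength: float = 1.0,
    seed: Optional[int] = None,
) -> dict:
    """Three binary series with a known directed lag-1 coupling.

    coupling:
      'none'   — mutually independent fair-coin series;
      'y_to_x' — x copies y's previous symbol with probability ``strength``;
      'x_to_y' — the reverse;
      'chain'  — y -> z -> x, each link at ``strength`` (so the y -> x
                 influence is entirely mediated by z).
    """
    if length < 50:
        raise ValueError("length must be >= 50")
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    def coin(size):
        return rng.integers(0, 2, size=size).astype(np.uint8)

    def copy_with(source, strength):
        out = coin(len(source))
        take = rng.random(len(source)) < strength
        out[1:][take[1:]] = source[:-1][take[1:]]
        return out

    if coupling == "none":
        x, y, z = coin(length), coin(length), coin(length)
    elif coupling == "y_to_x":
        y, z = coin(length), coin(length)
        x = copy_with(y, strength)
    elif coupling == "x_to_y":
        x, z = coin(length), coin(length)
        y = copy_with(x, strength)
    elif coupling == "chain":
        # a persistent (sticky) driver, so the mediated y -> z -> x path is
        # visible to a first-order embedding while conditioning on z removes it
        y = np.empty(length, dtype=np.uint8)
        y[0] = coin(1)[0]
        flips = rng.random(length) < 0.2
        for t in range(1, length):
            y[t] = (1 - y[t - 1]) if flips[t] else y[t - 1]
        z = copy_with(y, strength)
        x = copy_with(z, strength)
    else:
        raise ValueError(f"unknown coupling {coupling!r}")
    return {"x": x, "y": y, "z": z}
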