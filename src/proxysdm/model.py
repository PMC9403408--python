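"""Extended spatial Durbin panel model of monthly firearm ownership.

The model relates the ownership fraction Y_m of n states in month m to its
spatial lag, its own value 12 months earlier (and that value's spatial lag),
the two proxies observed the month before (background checks per capita, X1,
and fraction of suicides with firearms, X2) with separate coefficients for
high- and low-survey-response states, spatially lagged proxies, a linear
yearly trend, and class-specific intercepts:

    Y_m = rho W_m Y_m + tau Y_{m-12} + eta W_m Y_{m-12}
        + phi1_H X1H_{m-1} + phi1_L X1L_{m-1}
        + phi2_H X2H_{m-1} + phi2_L X2L_{m-1}
        + psi1 W X1_{m-1} + psi2 W X2_{m-1}
        + gamma d + alpha_H i_H + alpha_L i_L + eps,

with eps ~ N(0, sigma2 I). The contemporaneous spatial term makes the system
implicit; each month is resolved by solving (I - rho W) Y = rhs. The weight
matrix W is constant within a calendar year. Superscript-H vectors carry the
proxy entries of high-response states and zeros elsewhere (symmetrically L),
so the class split only affects the direct proxy terms and intercepts; the
spatial proxy lags psi W X use the unsplit vectors.

``simulate_panel`` iterates this recursion forward and doubles as the
synthetic-data engine; ``SpatialDurbinPanel`` is the user-facing model class
whose ``fit`` performs the October-stacked maximum-likelihood calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

import numpy as np

from .panel import StatePanel, register_result
from .weights import WeightMatrixSequence

__all__ = [
    "ModelParameters",
    "DELTA_FIELDS",
    "monthly_rhs",
    "solve_contemporaneous",
    "rho_bounds",
    "check_rho",
    "simulate_panel",
    "SpatialDurbinPanel",
]

# Order of the 11 stacked-regression coefficients (everything except rho and
# sigma2), matching the design-matrix column order in design.py.
DELTA_FIELDS = (
    "tau",
    "eta",
    "phi1_H",
    "phi1_L",
    "phi2_H",
    "phi2_L",
    "psi1",
    "psi2",
    "gamma",
    "alpha_H",
    "alpha_L",
)


@register_result
@dataclass
class ModelParameters:
    """The 13 scalars of the model.

    rho : contemporaneous spatial autoregression (dimensionless)
    tau, eta : 12-month own and spatial memory of ownership
    phi1_H, phi1_L : direct effect of background checks per capita
        (per checks/person/month), split by response class
    phi2_H, phi2_L : direct effect of the firearm-suicide fraction
    psi1, psi2 : spatially lagged proxy effects (unsplit)
    gamma : linear trend per year index
    alpha_H, alpha_L : class intercepts
    sigma2 : monthly noise variance (>= 0)
    """

    rho: float = 0.0
    tau: float = 0.0
    eta: float = 0.0
    phi1_H: float = 0.0
    phi1_L: float = 0.0
    phi2_H: float = 0.0
    phi2_L: float = 0.0
    psi1: float = 0.0
    psi2: float = 0.0
    gamma: float = 0.0
    alpha_H: float = 0.0
    alpha_L: float = 0.0
    sigma2: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be nonnegative")

    def delta(self) -> np.ndarray:
        """The 11 stacked coefficients in design-matrix column order."""
        return np.array([getattr(self, f) for f in DELTA_FIELDS])

    @classmethod
    def from_delta(
        cls, rho: float, delta: np.ndarray, sigma2: float
    ) -> "ModelParameters":
        kwargs = dict(zip(DELTA_FIELDS, np.asarray(delta, dtype=float)))
        return cls(rho=float(rho), sigma2=float(sigma2), **kwargs)

    def names(self) -> list[str]:
        return [f.name for f in fields(self)]


def rho_bounds(omega: np.ndarray) -> tuple[float, float]:
    """Feasible open interval for rho, (1/min(omega), 1/max(omega)).

    ``omega`` are eigenvalues of the (block) weight matrix; complex pairs
    enter through their real parts, the standard practice for row-stochastic
    W (whose largest eigenvalue is 1, giving an upper bound of 1). For the
    null matrix all eigenvalues vanish and the interval is unbounded.
    """
    re = np.real(np.asarray(omega))
    lo = 1.0 / re.min() if re.min() < 0 else -np.inf
    hi = 1.0 / re.max() if re.max() > 0 else np.inf
    return lo, hi


def check_rho(rho: float, omega: np.ndarray) -> None:
    lo, hi = rho_bounds(omega)
    if not lo < rho < hi:
        raise ValueError(
            f"rho={rho} outside the spectral interval ({lo:.6g}, {hi:.6g})"
        )


def monthly_rhs(
    params: ModelParameters,
    W: np.ndarray,
    Y_lag12: np.ndarray,
    X1_lag1: np.ndarray,
    X2_lag1: np.ndarray,
    year_dummy: int,
    high_mask: np.ndarray,
    W_x: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Right-hand side of the monthly equation, excluding rho*W*Y and noise.

    The H/L coefficients multiply only the matching units' proxy entries
    (zeros elsewhere); the spatial proxy lags use the unsplit vectors.
    ``W_x`` is the weight matrix paired with the lagged proxies (the matrix
    of the proxies' own month); it differs from ``W`` only when month m-1
    falls in the previous calendar year, and defaults to ``W``.
    """
    W = np.asarray(W, dtype=float)
    W_x = W if W_x is None else np.asarray(W_x, dtype=float)
    y = np.asarray(Y_lag12, dtype=float)
    x1 = np.asarray(X1_lag1, dtype=float)
    x2 = np.asarray(X2_lag1, dtype=float)
    hm = np.asarray(high_mask, dtype=bool)
    n = len(y)
    if W.shape != (n, n) or x1.shape != (n,) or x2.shape != (n,) or hm.shape != (n,):
        raise ValueError("dimension mismatch in monthly_rhs inputs")
    lm = ~hm
    return (
        params.tau * y
        + params.eta * (W @ y)
        + params.phi1_H * (x1 * hm)
        + params.phi1_L * (x1 * lm)
        + params.phi2_H * (x2 * hm)
        + params.phi2_L * (x2 * lm)
        + params.psi1 * (W_x @ x1)
        + params.psi2 * (W_x @ x2)
        + params.gamma * year_dummy
        + params.alpha_H * hm
        + params.alpha_L * lm
    )


def solve_contemporaneous(
    params: ModelParameters, W: np.ndarray, rhs: np.ndarray
) -> np.ndarray:
    """Solve (I - rho W) Y = rhs for the contemporaneous ownership vector."""
    rho = params.rho
    if rho == 0.0:
        return np.array(rhs, dtype=float)
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    A = np.eye(n) - rho * W
    try:
        return np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        lo, hi = rho_bounds(np.linalg.eigvals(W))
        raise ValueError(
            f"(I - rho W) singular at rho={rho}; spectral interval is "
            f"({lo:.6g}, {hi:.6g})"
        ) from None


def simulate_panel(
    params: ModelParameters,
    Wseq: WeightMatrixSequence,
    X1: np.ndarray,
    X2: np.ndarray,
    Y_init: np.ndarray,
    seed: Optional[int] = None,
    high_mask: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the model forward over all M months.

    Parameters
    ----------
    X1, X2 : ndarray, shape (n, M)
        Monthly proxy series covering the whole simulated span; month m's
        equation uses the proxies of month m-1 (the first month reuses its
        own value, an edge convention shared with the predictor).
    Y_init : ndarray, shape (n, 12)
        Ownership for the 12 months of the virtual burn-in year preceding
        the panel; supplies Y_{m-12} for the first simulated year.
    seed : int, optional
        Seeds the Gaussian noise (variance ``params.sigma2``); omit or set
        sigma2=0 for a noiseless trajectory.

    Returns
    -------
    Y : ndarray, shape (n, M)
        Simulated monthly ownership (not clipped to [0, 1]).
    october : ndarray, shape (n, T)
        The October columns, the synthetic analogue of annual survey anchors.
    """
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    Y_init = np.asarray(Y_init, dtype=float)
    n, M = X1.shape
    if X2.shape != (n, M) or Y_init.shape != (n, 12):
        raise ValueError("X1, X2 must be (n, M) and Y_init (n, 12)")
    if M % 12 != 0:
        raise ValueError("simulation span must cover whole years")
    T = M // 12
    if Wseq.n != n or Wseq.T < T:
        raise ValueError("weight sequence does not match panel dimensions")
    if high_mask is None:
        high_mask = np.ones(n, dtype=bool)
    check_rho(params.rho, Wseq.eigenvalues())

    rng = np.random.default_rng(seed)
    sd = np.sqrt(params.sigma2)
    Y = np.empty((n, M))
    for m in range(M):
        t = m // 12
        W = Wseq.matrices[t]
        y_lag = Y[:, m - 12] if m >= 12 else Y_init[:, m]
        x1 = X1[:, m - 1] if m >= 1 else X1[:, 0]
        x2 = X2[:, m - 1] if m >= 1 else X2[:, 0]
        W_x = Wseq.matrices[max(m - 1, 0) // 12]
        rhs = monthly_rhs(params, W, y_lag, x1, x2, t, high_mask, W_x=W_x)
        if sd > 0:
            rhs = rhs + rng.normal(0.0, sd, size=n)
        Y[:, m] = solve_contemporaneous(params, W, rhs)
    october = Y[:, 9::12].copy()  # month index 9 = October within each year
    return Y, october


class SpatialDurbinPanel:
    """Spatial Durbin panel model of ownership, built from a StatePanel.

    Parameters
    ----------
    panel : StatePanel
        Monthly proxies, annual October survey anchors, populations,
        centroids and the H/L response split.
    weights : WeightMatrixSequence, optional
        One spatial weight matrix per survey year. Defaults to the
        population-over-distance gravity matrix built from the panel's own
        populations and centroid distances.

    ``fit`` stacks the October observations and maximizes the concentrated
    likelihood over the spatial parameter, returning an
    :class:`~proxysdm.likelihood.SDMResults`.
    """

    def __init__(
        self, panel: StatePanel, weights: Optional[WeightMatrixSequence] = None
    ):
        if weights is None:
            from .weights import build_population_distance_W, pairwise_distance

            weights = build_population_distance_W(
                panel.populations,
                pairwise_distance(panel.centroids),
                year_index=list(panel.years),
            )
        if weights.n != panel.n:
            raise ValueError("weight matrices do not match the panel's unit count")
        self.panel = panel
        self.weights = weights

    @classmethod
    def from_tables(
        cls,
        proxy_table,
        survey_table,
        population_table,
        centroid_table,
        respondent_threshold: int = 10,
    ) -> "SpatialDurbinPanel":
        from .panel import read_panel

        panel = read_panel(
            proxy_table,
            survey_table,
            population_table,
            centroid_table,
            respondent_threshold,
        )
        return cls(panel)

    def fit(self, **options):
        """Maximum-likelihood calibration on the stacked October design.

        Keyword options are forwarded to :func:`proxysdm.likelihood.fit_mle`
        (``logdet_method``, ``n_draws``, ``order``, ``seed``, ``xtol``).
        """
        from .design import assemble_stack
        from .likelihood import SDMResults, fit_mle

        design = assemble_stack(self.panel, self.weights)
        result = fit_mle(design, **options)
        return SDMResults(self, design, result)

    def simulate(
        self,
        params: ModelParameters,
        seed: Optional[int] = None,
        Y_init: Optional[np.ndarray] = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Simulate a monthly ownership trajectory under ``params``.

        The burn-in year defaults to the first survey year's October values
        copied across its 12 months, mirroring the predictor's
        initialization.
        """
        if Y_init is None:
            y0 = self.panel.survey_Y[:, 0]
            if np.isnan(y0).any():
                raise ValueError(
                    "first survey year has missing values; supply Y_init"
                )
            Y_init = np.tile(y0[:, None], (1, 12))
        return simulate_panel(
            params,
            self.weights,
            self.panel.X1,
            self.panel.X2,
            Y_init,
            seed=seed,
            high_mask=self.panel.high_mask(),
        )
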