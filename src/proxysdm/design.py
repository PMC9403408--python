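"""Stacked October design for maximum-likelihood calibration.

Survey anchors of ownership exist only for October, so the monthly model is
estimated on a stack of October cross-sections: for each of the T-1 target
years 2..T, the response block is that year's October survey vector and the
regressors combine the previous October (the 12-month lag), September's
proxies of the target year (the 1-month lag), their spatial lags under that
year's weight matrix, the year dummy and the H/L intercept indicators. The
result is a ((T-1)*n)-row system Y = rho W Y + Z delta + eps with W block
diagonal (one year's matrix per block).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import StatePanel
from .weights import WeightMatrixSequence

__all__ = ["StackedDesign", "assemble_stack", "Z_COLUMNS"]

# Column order of the stacked design matrix; matches model.DELTA_FIELDS.
Z_COLUMNS = (
    "Y_L",
    "WY_L",
    "X1_H",
    "X1_L",
    "X2_H",
    "X2_L",
    "WX1",
    "WX2",
    "d",
    "i_H",
    "i_L",
)


@dataclass
class StackedDesign:
    """The stacked estimation system.

    Y : ((T-1)*n,) October ownership, years 2..T.
    Z : ((T-1)*n, 11) regressors in ``Z_COLUMNS`` order.
    Wblocks : (T-1, n, n) per-year weight matrices (the diagonal blocks).
    WY : ((T-1)*n,) the block-diagonal W applied to Y.
    omega : eigenvalues of the block-diagonal W (union of block spectra).
    is_null : True for the all-zero null weight matrix.
    """

    Y: np.ndarray
    Z: np.ndarray
    Wblocks: np.ndarray
    WY: np.ndarray
    omega: np.ndarray
    is_null: bool = False
    year_index: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        N = self.Y.shape[0]
        K, n, _ = self.Wblocks.shape
        if N != K * n:
            raise ValueError("row count must equal (T-1)*n")
        if self.Z.shape != (N, len(Z_COLUMNS)):
            raise ValueError(f"Z must have shape ({N}, {len(Z_COLUMNS)})")

    @property
    def n_obs(self) -> int:
        return self.Y.shape[0]

    @property
    def n_units(self) -> int:
        return self.Wblocks.shape[1]

    def Wblock_dense(self) -> np.ndarray:
        """Materialize the block-diagonal stacked weight matrix."""
        K, n, _ = self.Wblocks.shape
        W = np.zeros((K * n, K * n))
        for k in range(K):
            W[k * n : (k + 1) * n, k * n : (k + 1) * n] = self.Wblocks[k]
        return W

    def apply_W(self, v: np.ndarray) -> np.ndarray:
        """Block-diagonal matrix-vector product without materializing W."""
        K, n, _ = self.Wblocks.shape
        return np.einsum("kij,kj->ki", self.Wblocks, v.reshape(K, n)).ravel()


def assemble_stack(
    panel: StatePanel, Wseq: WeightMatrixSequence
) -> StackedDesign:
    """Build the stacked October design from a panel and weight sequence."""
    n, T = panel.n, panel.T
    if T < 2:
        raise ValueError("need at least 2 survey years to stack October lags")
    if Wseq.n != n or Wseq.T < T:
        raise ValueError("weight sequence does not match the panel")
    hm = panel.high_mask().astype(float)
    lm = 1.0 - hm

    first_year = panel.years[0]
    # proxy month indices: September of target year t (0-based year position)
    def _sep(t: int) -> int:
        return panel.month_index(first_year + t, 9)

    Yrows, Zrows, blocks = [], [], []
    for t in range(1, T):
        y_t = panel.survey_Y[:, t]
        y_lag = panel.survey_Y[:, t - 1]
        for vec, yr in [(y_t, panel.years[t]), (y_lag, panel.years[t - 1])]:
            if np.isnan(vec).any():
                unit = panel.unit_ids[int(np.flatnonzero(np.isnan(vec))[0])]
                raise ValueError(
                    f"missing survey anchor for unit {unit}, year {yr}"
                )
        W = Wseq.matrices[t]
        x1 = panel.X1[:, _sep(t)]
        x2 = panel.X2[:, _sep(t)]
        Z = np.column_stack(
            [
                y_lag,
                W @ y_lag,
                x1 * hm,
                x1 * lm,
                x2 * hm,
                x2 * lm,
                W @ x1,
                W @ x2,
                np.full(n, float(t)),
                hm,
                lm,
            ]
        )
        Yrows.append(y_t)
        Zrows.append(Z)
        blocks.append(W)

    Wblocks = np.stack(blocks)
    design = StackedDesign(
        Y=np.concatenate(Yrows),
        Z=np.vstack(Zrows),
        Wblocks=Wblocks,
        WY=np.empty(0),
        omega=np.empty(0),
        is_null=Wseq.is_null,
        year_index=list(panel.years[1:]),
    )
    design.WY = design.apply_W(design.Y)
    design.omega = np.concatenate([np.linalg.eigvals(W) for W in blocks])
    return design
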