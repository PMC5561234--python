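"""Cross-basis construction: the tensor-product design matrix of a DLNM.

The cross-basis encodes an exposure's nonlinear value-response and nonlinear
lag-response simultaneously. With value-basis columns ``R_j`` and lag-basis
columns ``C_k`` evaluated at integer lags ``l = 0..L``, the design entry for
day ``t`` and column ``(j, k)`` is

    sum_{l=0}^{L} R_j(x_{t-l}) * C_k(l)

Rows with index below ``L`` lack full lag history; they are emitted as NaN
and flagged invalid so no fit ever uses them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .basis_functions import BasisConfig, evaluate_basis, resolve_knots

__all__ = ["CrossBasis", "build_cross_basis"]


@dataclass
class CrossBasis:
    """A fitted cross-basis: design matrix plus the metadata to predict from it."""

    exposure_name: str
    value_basis: BasisConfig
    lag_basis: BasisConfig
    max_lag: int
    matrix: np.ndarray  # n_days x (v_x * v_l); rows < valid_from are NaN
    valid_from: int
    column_order: list[tuple[int, int]]  # (value index j, lag index k), 0-based
    series_range: tuple[float, float]

    @property
    def column_names(self) -> list[str]:
        return [
            f"{self.exposure_name}:v{j + 1}:l{k + 1}" for j, k in self.column_order
        ]

    def to_dict(self) -> dict:
        """Serializable metadata (no design matrix) for prediction reuse."""
        return {
            "exposure_name": self.exposure_name,
            "value_basis": self.value_basis.to_dict(),
            "lag_basis": self.lag_basis.to_dict(),
            "max_lag": self.max_lag,
            "column_order": [list(jk) for jk in self.column_order],
            "series_range": list(self.series_range),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CrossBasis":
        vb = BasisConfig.from_dict(d["value_basis"])
        lb = BasisConfig.from_dict(d["lag_basis"])
        return cls(
            exposure_name=d["exposure_name"],
            value_basis=vb,
            lag_basis=lb,
            max_lag=int(d["max_lag"]),
            matrix=np.empty((0, vb.ncols * lb.ncols)),
            valid_from=int(d["max_lag"]),
            column_order=[tuple(jk) for jk in d["column_order"]],
            series_range=tuple(d["series_range"]),
        )


def build_cross_basis(
    series: Sequence[float],
    value_basis: BasisConfig,
    lag_basis: BasisConfig,
    max_lag: int,
    exposure_name: str = "exposure",
    dates: Sequence | None = None,
) -> CrossBasis:
    """Build the cross-basis design matrix for one exposure series.

    Parameters
    ----------
    series:
        Daily exposure values, oldest first.
    value_basis, lag_basis:
        Basis configs for the value and lag dimensions. Spline knots are
        resolved here (value basis on the series, lag basis on ``0..max_lag``)
        if not already set.
    max_lag:
        Largest lag ``L`` in days; lags run ``0..L`` inclusive.
    dates:
        Optional per-row labels used in error messages for non-finite values.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < max_lag + 1:
        raise ValueError(
            f"series of length {n} is shorter than max_lag + 1 = {max_lag + 1}"
        )
    bad = ~np.isfinite(x)
    if bad.any():
        idx = np.flatnonzero(bad)
        labels = [str(dates[i]) if dates is not None else f"index {i}" for i in idx[:10]]
        raise ValueError(f"non-finite exposure values at: {', '.join(labels)}")

    vb = resolve_knots(x, value_basis)
    lags = np.arange(max_lag + 1, dtype=float)
    lb = resolve_knots(lags, lag_basis)

    Q = evaluate_basis(x, vb)  # n x v_x
    C = evaluate_basis(lags, lb)  # (L+1) x v_l
    vx, vl = Q.shape[1], C.shape[1]
    L = max_lag

    acc = np.zeros((n - L, vx, vl))
    for l in range(L + 1):
        acc += Q[L - l : n - l, :, None] * C[l, None, :]
    matrix = np.full((n, vx * vl), np.nan)
    matrix[L:] = acc.reshape(n - L, vx * vl)  # value-major: (j=0,k=0),(j=0,k=1),...

    column_order = [(j, k) for j in range(vx) for k in range(vl)]
    return CrossBasis(
        exposure_name=exposure_name,
        value_basis=vb,
        lag_basis=lb,
        max_lag=L,
        matrix=matrix,
        valid_from=L,
        column_order=column_order,
        series_range=(float(x.min()), float(x.max())),
    )
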