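"""One-dimensional basis expansions for the value and lag dimensions.

Two families are supported:

* centred polynomials — columns ``(x - c)^1 ... (x - c)^df``, optionally
  preceded by a constant column;
* natural cubic splines — piecewise cubics constrained to zero second
  derivative at, and linearity beyond, their boundary knots, built from the
  truncated-power representation.

A spline basis with ``k`` interior knots spans ``k + 1`` columns
(``df = interior + 1``): the two natural constraints absorb two of the four
cubic degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

POLYNOMIAL = "polynomial"
NATURAL_CUBIC_SPLINE = "natural_cubic_spline"

__all__ = [
    "BasisConfig",
    "evaluate_basis",
    "resolve_knots",
    "POLYNOMIAL",
    "NATURAL_CUBIC_SPLINE",
]


@dataclass(frozen=True)
class BasisConfig:
    """Specification of a one-dimensional basis.

    Parameters
    ----------
    family:
        ``"polynomial"`` or ``"natural_cubic_spline"``.
    df:
        Number of basis columns excluding any intercept column. For the
        spline family, ``df = number of interior knots + 1``.
    center:
        Polynomial centring constant, in the variable's units. The centred
        basis is exactly zero at ``x = center``. Ignored for splines.
    knots:
        Interior knots (splines only), strictly increasing and strictly
        inside the boundary knots. ``None`` until resolved from data.
    boundary_knots:
        ``(low, high)`` pair (splines only). ``None`` until resolved.
    intercept:
        Prepend a constant column of ones. Used for lag bases, where the
        constant column carries same-day (lag-0) effects.
    """

    family: str
    df: int
    center: float | None = None
    knots: tuple[float, ...] | None = None
    boundary_knots: tuple[float, float] | None = None
    intercept: bool = False

    def __post_init__(self) -> None:
        if self.family not in (POLYNOMIAL, NATURAL_CUBIC_SPLINE):
            raise ValueError(f"unknown basis family {self.family!r}")
        if self.df < 1 and not (self.df == 0 and self.intercept):
            raise ValueError("df must be >= 1 (df=0 allowed only with intercept)")
        if self.knots is not None:
            object.__setattr__(self, "knots", tuple(float(k) for k in self.knots))
        if self.boundary_knots is not None:
            lo, hi = self.boundary_knots
            if not lo < hi:
                raise ValueError("boundary_knots must be an increasing pair")
            object.__setattr__(self, "boundary_knots", (float(lo), float(hi)))
        if self.knots is not None and self.boundary_knots is not None:
            lo, hi = self.boundary_knots
            ks = np.asarray(self.knots)
            if len(ks) and not (np.all(np.diff(ks) > 0) and ks[0] > lo and ks[-1] < hi):
                raise ValueError(
                    "interior knots must be strictly increasing and strictly "
                    "inside the boundary knots"
                )
            if self.df != len(ks) + 1:
                raise ValueError(
                    f"spline df={self.df} inconsistent with {len(ks)} interior "
                    f"knots (expected df = interior + 1 = {len(ks) + 1})"
                )

    @property
    def ncols(self) -> int:
        """Total number of basis columns including the intercept, if any."""
        return self.df + int(self.intercept)

    @property
    def resolved(self) -> bool:
        if self.family == POLYNOMIAL:
            return True
        return self.knots is not None and self.boundary_knots is not None

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "df": self.df,
            "center": self.center,
            "knots": list(self.knots) if self.knots is not None else None,
            "boundary_knots": list(self.boundary_knots)
            if self.boundary_knots is not None
            else None,
            "intercept": self.intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BasisConfig":
        return cls(
            family=d["family"],
            df=int(d["df"]),
            center=d.get("center"),
            knots=tuple(d["knots"]) if d.get("knots") is not None else None,
            boundary_knots=tuple(d["boundary_knots"])
            if d.get("boundary_knots") is not None
            else None,
            intercept=bool(d.get("intercept", False)),
        )


def _polynomial_basis(x: np.ndarray, config: BasisConfig) -> np.ndarray:
    c = 0.0 if config.center is None else float(config.center)
    z = x - c
    return np.column_stack([z**p for p in range(1, config.df + 1)]) if config.df else np.empty((len(x), 0))


def _natural_spline_basis(x: np.ndarray, config: BasisConfig) -> np.ndarray:
    lo, hi = config.boundary_knots
    knots = np.array([lo, *(config.knots or ()), hi], dtype=float)
    K = len(knots)

    def trunc3(v: np.ndarray, xi: float) -> np.ndarray:
        return np.clip(v - xi, 0.0, None) ** 3

    def d(k: int) -> np.ndarray:
        return (trunc3(x, knots[k]) - trunc3(x, knots[K - 1])) / (knots[K - 1] - knots[k])

    cols = [x.astype(float)]
    dlast = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dlast)
    return np.column_stack(cols)


def evaluate_basis(x: Sequence[float], config: BasisConfig) -> np.ndarray:
    """Evaluate the basis at ``x``, returning a ``len(x) x config.ncols`` matrix.

    Each row depends only on the corresponding entry of ``x``, so the matrix
    is invariant to the ordering of evaluation points.
    """
    xa = np.asarray(x, dtype=float)
    if xa.ndim != 1:
        xa = xa.ravel()
    if config.family == NATURAL_CUBIC_SPLINE and not config.resolved:
        raise ValueError(
            "spline knots are unresolved; call resolve_knots(values, config) first"
        )
    if config.family == POLYNOMIAL:
        core = _polynomial_basis(xa, config)
    else:
        core = _natural_spline_basis(xa, config)
    if config.intercept:
        core = np.column_stack([np.ones(len(xa)), core])
    return core


def resolve_knots(values: Sequence[float], config: BasisConfig) -> BasisConfig:
    """Place spline knots from data: boundary at min/max, interior at quantiles.

    With ``df`` columns the ``df - 1`` interior knots sit at the empirical
    quantiles ``k/df`` for ``k = 1..df-1``. Already-resolved configs are
    returned unchanged (idempotent). Polynomial configs pass through.
    """
    if config.family == POLYNOMIAL:
        return config
    if config.resolved:
        return config
    vals = np.asarray(values, dtype=float)
    lo, hi = float(np.min(vals)), float(np.max(vals))
    if not hi > lo:
        raise ValueError("cannot place spline knots on constant values (range = 0)")
    n_interior = config.df - 1
    if n_interior:
        qs = np.arange(1, n_interior + 1) / config.df
        interior = tuple(float(q) for q in np.quantile(vals, qs))
        if len(set(interior)) != n_interior or not all(lo < k < hi for k in interior):
            raise ValueError(
                "quantile knots are degenerate for these values; reduce df"
            )
    else:
        interior = ()
    return replace(config, knots=interior, boundary_knots=(lo, hi))
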