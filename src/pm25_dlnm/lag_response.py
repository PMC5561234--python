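"""Reference-centred relative-risk surfaces from a fitted DLNM.

Given cross-basis coefficients beta and their covariance Sigma, the log
relative risk of exposure ``x`` versus the reference ``x0`` at lag ``l`` is

    log RR(x, l) = sum_{j,k} beta_{jk} [R_j(x) - R_j(x0)] C_k(l)

i.e. a linear contrast ``c' beta`` whose variance is ``c' Sigma c`` (delta
method on the log scale); 95% intervals are Wald, exponentiated. The
cumulative relative risk over the lag window sums the per-lag contrasts, so
it equals the product of the per-lag RRs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis_functions import evaluate_basis
from .cross_basis import CrossBasis
from .model_fit import FitResult

__all__ = ["RRSurface", "predict_rr", "export_surface", "surface_from_long", "PROBE_VALUES"]

#: Default exposure probe grid (mcg/m^3) for the headline wide table.
PROBE_VALUES = (10.0, 50.0, 100.0, 150.0, 200.0)
_Z95 = 1.959963984540054


@dataclass
class RRSurface:
    """Grid of relative risks over (exposure value x lag), centred at a reference."""

    exposure_values: np.ndarray
    lags: np.ndarray
    reference: float
    rr: np.ndarray  # values x lags
    ci_low: np.ndarray
    ci_high: np.ndarray
    cumulative_rr: np.ndarray  # per exposure value
    cumulative_ci_low: np.ndarray
    cumulative_ci_high: np.ndarray
    extrapolated: np.ndarray  # bool per exposure value


def predict_rr(
    fit: FitResult,
    cb: CrossBasis,
    values,
    reference: float | None = None,
) -> RRSurface:
    """Predict the RR surface for one exposure from its fitted cross-basis.

    ``fit`` must contain every cross-basis column by name; coefficients and
    covariance blocks are aligned by those names. Values outside the training
    exposure range are computed but flagged as extrapolation.
    """
    values = np.atleast_1d(np.asarray(values, dtype=float))
    if reference is None:
        reference = cb.value_basis.center if cb.value_basis.center is not None else 30.0
    names = cb.column_names
    try:
        idx = [fit.column_names.index(n) for n in names]
    except ValueError as exc:
        raise ValueError(
            f"fit does not contain cross-basis columns for {cb.exposure_name!r}: {exc}"
        ) from exc
    beta = fit.coefficients[idx]
    Sig = fit.covariance[np.ix_(idx, idx)]

    vx = cb.value_basis.ncols
    vl = cb.lag_basis.ncols
    lags = np.arange(cb.max_lag + 1)
    Rv = evaluate_basis(values, cb.value_basis)  # nx x vx
    R0 = evaluate_basis([reference], cb.value_basis)[0]
    C = evaluate_basis(lags.astype(float), cb.lag_basis)  # nl x vl
    D = Rv - R0

    nx, nl = len(values), len(lags)
    logrr = np.empty((nx, nl))
    se = np.empty((nx, nl))
    logcum = np.empty(nx)
    secum = np.empty(nx)
    for i in range(nx):
        contrasts = (D[i][:, None, None] * C.T[None, :, :]).reshape(vx * vl, nl)
        logrr[i] = beta @ contrasts
        se[i] = np.sqrt(np.einsum("ij,ik,kj->j", contrasts, Sig, contrasts))
        csum = contrasts.sum(axis=1)
        logcum[i] = beta @ csum
        secum[i] = np.sqrt(csum @ Sig @ csum)

    lo, hi = cb.series_range
    return RRSurface(
        exposure_values=values,
        lags=lags,
        reference=float(reference),
        rr=np.exp(logrr),
        ci_low=np.exp(logrr - _Z95 * se),
        ci_high=np.exp(logrr + _Z95 * se),
        cumulative_rr=np.exp(logcum),
        cumulative_ci_low=np.exp(logcum - _Z95 * secum),
        cumulative_ci_high=np.exp(logcum + _Z95 * secum),
        extrapolated=(values < lo) | (values > hi),
    )


def export_surface(surface: RRSurface) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Export a surface as (long grid, wide exposure-by-lag pivot).

    The long table has one row per (exposure, lag) with the RR and its 95%
    interval, plus the cumulative RR repeated per exposure. The wide table is
    the human-readable pivot with cells ``rr (lo,hi)`` rounded to 2 decimals.
    """
    nx, nl = surface.rr.shape
    long = pd.DataFrame(
        {
            "exposure": np.repeat(surface.exposure_values, nl),
            "lag": np.tile(surface.lags, nx),
            "rr": surface.rr.ravel(),
            "ci_low": surface.ci_low.ravel(),
            "ci_high": surface.ci_high.ravel(),
            "cumulative_rr": np.repeat(surface.cumulative_rr, nl),
            "cumulative_ci_low": np.repeat(surface.cumulative_ci_low, nl),
            "cumulative_ci_high": np.repeat(surface.cumulative_ci_high, nl),
            "reference": surface.reference,
            "extrapolated": np.repeat(surface.extrapolated, nl),
        }
    )
    wide = pd.DataFrame(
        {
            f"lag_{l}": [
                f"{surface.rr[i, l]:.2f} ({surface.ci_low[i, l]:.2f},{surface.ci_high[i, l]:.2f})"
                for i in range(nx)
            ]
            for l in range(nl)
        },
        index=pd.Index(surface.exposure_values, name="pm25"),
    )
    return long, wide


def surface_from_long(long: pd.DataFrame) -> RRSurface:
    """Rebuild an RRSurface from its long-format export (round-trip inverse)."""
    values = np.unique(long["exposure"].to_numpy())
    lags = np.unique(long["lag"].to_numpy().astype(int))
    piv = long.set_index(["exposure", "lag"]).sort_index()
    shape = (len(values), len(lags))

    def grid(col: str) -> np.ndarray:
        return piv[col].to_numpy(dtype=float).reshape(shape)

    per_val = piv.groupby(level="exposure").first()
    return RRSurface(
        exposure_values=values,
        lags=lags,
        reference=float(long["reference"].iloc[0]),
        rr=grid("rr"),
        ci_low=grid("ci_low"),
        ci_high=grid("ci_high"),
        cumulative_rr=per_val["cumulative_rr"].to_numpy(dtype=float),
        cumulative_ci_low=per_val["cumulative_ci_low"].to_numpy(dtype=float),
        cumulative_ci_high=per_val["cumulative_ci_high"].to_numpy(dtype=float),
        extrapolated=per_val["extrapolated"].to_numpy(dtype=bool),
    )
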