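"""Stage 1: satellite AOD gap filling by per-cell linear regression.

For each grid cell, an ordinary least-squares line is fitted through the
(reanalysis, satellite) day pairs of one year; missing satellite values are
then replaced by ``alpha_s + beta_s * reanalysis``.  Cells with too few
paired days (or a degenerate regressor) fall back to coefficients pooled
over their 8-neighborhood, else to a domain-pooled regression, and the
provenance of every output value is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import FieldStack

__all__ = ["ImputationCoeffs", "fit_gridwise_regression", "impute_aod", "imputation_diagnostics",
           "PROV_OBSERVED", "PROV_IMPUTED", "PROV_FALLBACK", "PROV_MISSING"]

PROV_OBSERVED, PROV_IMPUTED, PROV_FALLBACK, PROV_MISSING = 0, 1, 2, 3


@dataclass
class ImputationCoeffs:
    """Per-cell link coefficients and regression diagnostics."""

    alpha: np.ndarray       # intercept (AOD units); NaN where undefined
    beta: np.ndarray        # slope (unitless); NaN where undefined
    n: np.ndarray           # paired days used
    r2: np.ndarray          # coefficient of determination
    p_value: np.ndarray     # two-sided t-test p-value for the slope
    degenerate: np.ndarray  # True where the regressor had (near) zero variance
    n_min: int
    # domain-pooled fallback line (fitted over all paired cell-days)
    pooled_alpha: float = np.nan
    pooled_beta: float = np.nan

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.beta)


def fit_gridwise_regression(satellite: FieldStack, reanalysis: FieldStack, n_min: int = 10) -> ImputationCoeffs:
    """Cell-wise OLS of satellite on reanalysis over paired days.

    Cells with fewer than ``n_min`` paired days, or with a constant
    reanalysis series, are left undefined (NaN coefficients).  Everything is
    vectorized over cells via masked sums.
    """
    if satellite.grid != reanalysis.grid or satellite.dates != reanalysis.dates:
        raise ValueError("satellite and reanalysis must share grid and calendar")
    pair = (~satellite.mask) & (~reanalysis.mask)
    w = pair.astype(float)
    x = np.where(pair, reanalysis.values, 0.0)
    y = np.where(pair, satellite.values, 0.0)
    n = w.sum(axis=0)
    sx = (w * x).sum(axis=0)
    sy = (w * y).sum(axis=0)
    sxx = (w * x * x).sum(axis=0)
    sxy = (w * x * y).sum(axis=0)
    syy = (w * y * y).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ssx = sxx - sx * sx / n
        ssy = syy - sy * sy / n
        sxy_c = sxy - sx * sy / n
        beta = sxy_c / ssx
        alpha = (sy - beta * sx) / n
        # r2 = explained/total; guard zero-variance responses
        r2 = np.where(ssy > 0, (sxy_c**2) / (ssx * ssy), np.nan)
        rss = ssy - beta * sxy_c
        dof = n - 2
        se_beta = np.sqrt(np.maximum(rss, 0.0) / np.maximum(dof, 1) / ssx)
        tstat = beta / se_beta
    p = np.full(beta.shape, np.nan)
    ok_dof = dof > 0
    p[ok_dof] = 2.0 * stats.t.sf(np.abs(tstat[ok_dof]), dof[ok_dof])
    degenerate = (n >= 2) & (ssx <= 1e-12 * np.maximum(n, 1))
    undefined = (n < n_min) | degenerate | ~np.isfinite(beta)
    for arr in (alpha, beta, r2, p):
        arr[undefined] = np.nan
    r2 = np.clip(r2, 0.0, 1.0)

    # domain-pooled fallback line over all paired cell-days
    N = n.sum()
    pooled_alpha = pooled_beta = np.nan
    if N >= 2:
        SX, SY, SXX, SXY = sx.sum(), sy.sum(), sxx.sum(), sxy.sum()
        denom = SXX - SX * SX / N
        if denom > 0:
            pooled_beta = (SXY - SX * SY / N) / denom
            pooled_alpha = (SY - pooled_beta * SX) / N
    return ImputationCoeffs(alpha, beta, n.astype(int), r2, p, degenerate, n_min,
                            float(pooled_alpha), float(pooled_beta))


def _neighborhood_fallback(coeffs: ImputationCoeffs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fill undefined cells from the mean of defined 8-neighbors, else pooled.

    Returns (alpha_fb, beta_fb, used_fallback mask).  Cells that stay NaN
    (no neighbors and no pooled line) remain undefined.
    """
    alpha = coeffs.alpha.copy()
    beta = coeffs.beta.copy()
    need = ~coeffs.defined
    if need.any():
        ok = coeffs.defined.astype(float)
        a0 = np.where(coeffs.defined, coeffs.alpha, 0.0)
        b0 = np.where(coeffs.defined, coeffs.beta, 0.0)
        ksum = np.zeros_like(ok)
        asum = np.zeros_like(ok)
        bsum = np.zeros_like(ok)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                ksum += np.roll(np.roll(ok, di, axis=0), dj, axis=1) * _valid_shift(ok.shape, di, dj)
                asum += np.roll(np.roll(a0, di, axis=0), dj, axis=1) * _valid_shift(ok.shape, di, dj)
                bsum += np.roll(np.roll(b0, di, axis=0), dj, axis=1) * _valid_shift(ok.shape, di, dj)
        with np.errstate(invalid="ignore", divide="ignore"):
            a_nb = asum / ksum
            b_nb = bsum / ksum
        use_nb = need & (ksum > 0)
        alpha[use_nb] = a_nb[use_nb]
        beta[use_nb] = b_nb[use_nb]
        rest = need & ~(ksum > 0)
        if np.isfinite(coeffs.pooled_beta):
            alpha[rest] = coeffs.pooled_alpha
            beta[rest] = coeffs.pooled_beta
    return alpha, beta, need


def _valid_shift(shape: tuple[int, int], di: int, dj: int) -> np.ndarray:
    """Mask that blanks wrap-around rows/cols introduced by np.roll."""
    m = np.ones(shape)
    if di == 1:
        m[0, :] = 0.0
    elif di == -1:
        m[-1, :] = 0.0
    if dj == 1:
        m[:, 0] = 0.0
    elif dj == -1:
        m[:, -1] = 0.0
    return m


def impute_aod(satellite: FieldStack, reanalysis: FieldStack, coeffs: ImputationCoeffs) -> tuple[FieldStack, FieldStack]:
    """Fill satellite gaps with the per-cell regression prediction.

    Observed values are never altered.  Where the cell's own coefficients
    are undefined, neighborhood/pooled fallback coefficients are used and
    flagged.  Imputed values are clipped below at zero.  Returns
    ``(final_aod, provenance)`` where provenance codes are 0=observed,
    1=imputed, 2=fallback, 3=missing.
    """
    alpha_fb, beta_fb, was_fb = _neighborhood_fallback(coeffs)
    obs = ~satellite.mask
    pred = alpha_fb[None] + beta_fb[None] * np.where(reanalysis.mask, np.nan, reanalysis.values)
    pred = np.maximum(pred, 0.0)
    can_impute = (~reanalysis.mask) & np.isfinite(beta_fb)[None]
    out = np.where(obs, satellite.values, np.where(can_impute, pred, 0.0))
    mask = ~(obs | can_impute)
    prov = np.full(out.shape, PROV_MISSING, dtype=np.int8)
    prov[np.broadcast_to(~was_fb[None], out.shape) & can_impute] = PROV_IMPUTED
    prov[np.broadcast_to(was_fb[None], out.shape) & can_impute] = PROV_FALLBACK
    prov[obs] = PROV_OBSERVED
    out = np.where(mask, 0.0, out)
    final = FieldStack(satellite.grid, satellite.dates, out, mask)
    provenance = FieldStack(satellite.grid, satellite.dates, prov.astype(float),
                            np.zeros(out.shape, dtype=bool))
    return final, provenance


def imputation_diagnostics(coeffs: ImputationCoeffs, p_threshold: float = 0.01) -> dict:
    """Domain summaries of the per-cell regressions.

    Includes the fraction of defined cells whose slope p-value exceeds the
    confidence threshold used to judge the fits (default 0.01).
    """
    defined = coeffs.defined
    n_cells = defined.size
    out = {
        "n_cells": int(n_cells),
        "n_defined": int(defined.sum()),
        "n_degenerate": int(coeffs.degenerate.sum()),
        "coverage": float(defined.mean()),
        "mean_r2": float(np.nanmean(coeffs.r2)) if defined.any() else np.nan,
        "mean_slope": float(np.nanmean(coeffs.beta)) if defined.any() else np.nan,
        "mean_intercept": float(np.nanmean(coeffs.alpha)) if defined.any() else np.nan,
        "mean_n": float(coeffs.n[defined].mean()) if defined.any() else np.nan,
        "frac_p_above": float(np.mean(coeffs.p_value[defined] > p_threshold)) if defined.any() else np.nan,
        "p_threshold": p_threshold,
    }
    return out


def coeffs_table(coeffs: ImputationCoeffs) -> pd.DataFrame:
    """Flat per-cell table of coefficients (for CSV export)."""
    ni, nj = coeffs.alpha.shape
    ii, jj = np.meshgrid(np.arange(ni), np.arange(nj), indexing="ij")
    return pd.DataFrame({
        "cell_i": ii.ravel(), "cell_j": jj.ravel(),
        "alpha": coeffs.alpha.ravel(), "beta": coeffs.beta.ravel(),
        "n": coeffs.n.ravel(), "r2": coeffs.r2.ravel(), "p_value": coeffs.p_value.ravel(),
    })
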