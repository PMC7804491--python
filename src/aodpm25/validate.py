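"""Tenfold cross-validation, fit metrics and station-wise summaries.

The CV is random over station-day rows (matching the study design, not
leave-station-out): rows are partitioned into k near-equal folds; for each
fold the LME and GWR stages are refitted on the other k-1 folds and the
held-out rows predicted.  r2 is the squared Pearson correlation between
observed and predicted (not the regression R^2).  The AOD imputation stage
uses no PM2.5 and is therefore fitted once outside the CV loop — no leakage
can flow through it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stage2, stage3

__all__ = ["MetricSet", "kfold_split", "compute_metrics", "cross_validate",
           "stationwise_and_missing_day_eval"]


@dataclass
class MetricSet:
    """Agreement metrics between observed and predicted vectors."""

    n: int
    r2: float | None          # squared Pearson correlation; None if undefined
    rmse: float
    mae: float
    slope: float              # OLS slope of predicted on observed
    intercept: float
    m: float                  # forced-through-origin slope, sum(xy)/sum(x^2)
    status: str = "ok"

    def as_dict(self) -> dict:
        return {"n": self.n, "r2": self.r2, "rmse": self.rmse, "mae": self.mae,
                "slope": self.slope, "intercept": self.intercept, "m": self.m, "status": self.status}


def compute_metrics(observed, predicted) -> MetricSet:
    """r2 (squared Pearson), RMSE, MAE, OLS and forced-origin slopes."""
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    err = y - x
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    sxx = np.sum((x - x.mean()) ** 2)
    syy = np.sum((y - y.mean()) ** 2)
    m = float(np.sum(x * y) / np.sum(x * x)) if np.sum(x * x) > 0 else np.nan
    if sxx <= 0 or syy <= 0:
        return MetricSet(x.size, None, rmse, mae, np.nan, np.nan, m, status="degenerate: zero variance")
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    r2 = float((sxy**2) / (sxx * syy))
    slope = float(sxy / sxx)
    intercept = float(y.mean() - slope * x.mean())
    return MetricSet(x.size, r2, rmse, mae, slope, intercept, m)


def kfold_split(n: int, k: int = 10, seed: int = 0) -> np.ndarray:
    """Random partition of n rows into k folds with sizes differing by <= 1."""
    if n < k:
        raise ValueError(f"cannot split {n} rows into {k} folds")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    perm = rng.permutation(n)
    fold = np.empty(n, dtype=int)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    start = 0
    for f, size in enumerate(sizes):
        fold[perm[start:start + size]] = f
        start += size
    return fold


def cross_validate(table: pd.DataFrame, k_folds: int = 10, seed: int = 0,
                   fixed: tuple = stage2.DEFAULT_FIXED, random: tuple = stage2.DEFAULT_RANDOM,
                   k_min: int = stage3.K_MIN, run_stage3: bool = True,
                   floor: float = stage2.PM25_FLOOR) -> tuple[pd.DataFrame, dict]:
    """k-fold CV of stages 2 and 2+3 over the model-ready rows of a table.

    Rows with missing AOD are excluded (they cannot enter either stage).
    Returns ``(cv_table, metrics)`` with pooled held-out predictions for
    each stage; per fold, the GWR bandwidth is reselected on the training
    rows of each day.
    """
    df = table.dropna(subset=["pm25", "aod"]).reset_index(drop=True)
    fold = kfold_split(len(df), k_folds, seed)
    pred2 = np.full(len(df), np.nan)
    pred3 = np.full(len(df), np.nan)
    for f in range(k_folds):
        test = fold == f
        train = ~test
        fit = stage2.fit_lme(df[train], fixed=fixed, random=random)
        p2, _ = stage2.predict_rows(fit, df[test], floor=floor)
        pred2[test] = p2
        if run_stage3:
            resid = stage2.station_residuals(fit, df[train], floor=floor)
            fits = stage3.fit_gwr_all_days(resid, k_min=k_min)
            held = df[test].copy()
            held["_p2"] = p2
            corr = pd.Series(0.0, index=held.index)
            for d, g in held.groupby("date"):
                dayfit = fits.get(d)
                if dayfit is not None:
                    corr.loc[g.index] = stage3.predict_gwr_at_points(
                        dayfit, g["lat"].to_numpy(), g["lon"].to_numpy(), g["aod"].to_numpy())
            pred3[test] = np.maximum(p2 + corr.to_numpy(), floor)
    cv = df[["station_id", "date", "lat", "lon", "pm25", "aod", "aod_provenance"]].copy() \
        if "aod_provenance" in df else df[["station_id", "date", "lat", "lon", "pm25", "aod"]].copy()
    cv["fold"] = fold
    cv["pred_stage2"] = pred2
    metrics = {"stage2": compute_metrics(cv["pm25"], cv["pred_stage2"])}
    if run_stage3:
        cv["pred_stage3"] = pred3
        metrics["stage3"] = compute_metrics(cv["pm25"], cv["pred_stage3"])
    return cv, metrics


def stationwise_and_missing_day_eval(cv_table: pd.DataFrame, min_rows: int = 10) -> dict:
    """Per-station metrics and the imputed-AOD-day skill check.

    Returns a dict with a per-station metric table (CV predictions) and,
    when AOD provenance is recorded, a pooled MetricSet over rows whose AOD
    was imputed (satellite missing) — the skill the gap filling buys.
    """
    pred_col = "pred_stage3" if "pred_stage3" in cv_table else "pred_stage2"
    rows = []
    for sid, g in cv_table.groupby("station_id", sort=True):
        flag = "ok" if len(g) >= min_rows else "small-n"
        if len(g) >= 2:
            ms = compute_metrics(g["pm25"], g[pred_col])
            rows.append({"station_id": sid, **ms.as_dict(), "flag": flag})
        else:
            rows.append({"station_id": sid, "n": len(g), "flag": "small-n"})
    station_table = pd.DataFrame(rows)
    out = {"stations": station_table}
    if "aod_provenance" in cv_table:
        imputed = cv_table[cv_table["aod_provenance"].isin(["imputed", "fallback"])]
        if len(imputed) >= 2:
            out["imputed_aod"] = compute_metrics(imputed["pm25"], imputed[pred_col])
        else:
            out["imputed_aod"] = None
    return out
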