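"""Stage 3: daily geographically weighted regression of LME residuals on AOD.

At every calibration point (monitor) an intercept/slope pair is estimated by
weighted least squares, with compact-support bi-square weights whose radius
adapts to the distance of the k-th nearest calibration point.  The neighbor
count k is chosen per day by minimizing the small-sample-corrected AIC of
the local-regression smoother,

    AICc = 2 n ln(sigma_hat) + n ln(2 pi) + n (n + tr(S)) / (n - 2 - tr(S)),

with sigma_hat^2 = RSS/n and tr(S) the trace of the hat matrix.  Days with
too few calibration points fall back to a pooled ("global") OLS of residual
on AOD.  Prediction at unsampled grid cells re-centers the kernel at the
cell and applies the locally refitted coefficients to the cell's AOD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import DailyField, FieldStack, haversine_km

__all__ = [
    "GWRDayFit", "bisquare_weights", "adaptive_bandwidth", "fit_gwr_day",
    "select_bandwidth", "predict_gwr", "golden_section_k",
]

K_MIN = 6
BANDWIDTH_INFLATION = 1e-6
SINGULAR_TOL = 1e-10


def bisquare_weights(distances: np.ndarray, bandwidth: float) -> np.ndarray:
    """Bi-square kernel w = (1 - (d/h)^2)^2 for d < h, else 0."""
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    u = d / bandwidth
    w = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
    return w


def adaptive_bandwidth(target_lat: float, target_lon: float, cal_lat: np.ndarray,
                       cal_lon: np.ndarray, k: int, station_ids=None) -> float:
    """Distance to the k-th nearest calibration point, slightly inflated.

    Zero-distance points (the kernel center itself, when it is a calibration
    point) are excluded from the ranking, so the local fit always sees k
    neighbors plus the center — at least 3 effective points for the
    2-parameter fit once k >= 2.  The (1 + 1e-6) inflation guarantees the
    k-th neighbor receives positive weight.  Ties are broken
    deterministically by (distance, station_id).
    """
    if k < 2:
        raise ValueError("k must be at least 2 (>= 3 effective points including the center)")
    d = haversine_km(target_lat, target_lon, np.asarray(cal_lat), np.asarray(cal_lon))
    if station_ids is not None:
        order = np.lexsort((np.asarray(station_ids), d))
        ranked = d[order]
    else:
        ranked = np.sort(d, kind="stable")
    ranked = ranked[ranked > 0.0]
    if k > ranked.size:
        raise ValueError(f"k={k} exceeds {ranked.size} non-coincident calibration points")
    return float(ranked[k - 1]) * (1.0 + BANDWIDTH_INFLATION)


def _local_wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float, bool]:
    """Closed-form weighted least squares of y on (1, x).

    Returns (b0, b1, singular).  A (weighted) AOD variance below tolerance
    triggers the weighted-mean-only fallback (b1 = 0).
    """
    sw = w.sum()
    if sw <= 0:
        return np.nan, np.nan, True
    swx = (w * x).sum()
    swy = (w * y).sum()
    swxx = (w * x * x).sum()
    swxy = (w * x * y).sum()
    det = sw * swxx - swx * swx
    var_x = swxx / sw - (swx / sw) ** 2
    if var_x < SINGULAR_TOL or det <= 0:
        return swy / sw, 0.0, True
    b1 = (sw * swxy - swx * swy) / det
    b0 = (swy - b1 * swx) / sw
    return b0, b1, False


@dataclass
class GWRDayFit:
    """Per-day local fit at the calibration points."""

    date: object
    station_id: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    aod: np.ndarray
    residual: np.ndarray
    k: int
    bandwidth: np.ndarray          # per calibration point, km
    b0: np.ndarray
    b1: np.ndarray
    singular: np.ndarray           # points that fell back to weighted mean
    hat: np.ndarray                # hat value at each point
    fitted: np.ndarray
    trace_s: float
    rss: float
    aicc: float
    status: str = "gwr"            # "gwr" or "global"
    global_b0: float = np.nan
    global_b1: float = np.nan

    @property
    def n(self) -> int:
        return int(self.residual.size)


def _global_fallback(day: pd.DataFrame, date) -> GWRDayFit:
    """Pooled OLS of residual on AOD for sparse days."""
    x = day["aod"].to_numpy(dtype=float)
    y = day["residual"].to_numpy(dtype=float)
    b0, b1, _ = _local_wls(x, y, np.ones_like(x))
    fitted = b0 + b1 * x
    n = x.size
    return GWRDayFit(date, day["station_id"].to_numpy(), day["lat"].to_numpy(), day["lon"].to_numpy(),
                     x, y, k=0, bandwidth=np.full(n, np.nan), b0=np.full(n, b0), b1=np.full(n, b1),
                     singular=np.zeros(n, dtype=bool), hat=np.full(n, np.nan), fitted=fitted,
                     trace_s=np.nan, rss=float(np.sum((y - fitted) ** 2)), aicc=np.nan,
                     status="global", global_b0=float(b0), global_b1=float(b1))


def _prepare_day(day: pd.DataFrame) -> dict:
    """Extract arrays and the inter-point distance matrix once per day."""
    day = day.sort_values("station_id", kind="stable").reset_index(drop=True)
    lat = day["lat"].to_numpy(dtype=float)
    lon = day["lon"].to_numpy(dtype=float)
    return {
        "date": day["date"].iloc[0] if "date" in day else None,
        "sid": day["station_id"].to_numpy(),
        "lat": lat, "lon": lon,
        "x": day["aod"].to_numpy(dtype=float),
        "y": day["residual"].to_numpy(dtype=float),
        "dist": haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :]),
    }


def fit_gwr_day(day: pd.DataFrame, k: int, k_min: int = K_MIN) -> GWRDayFit:
    """Local WLS at every calibration point of one day.

    ``day`` needs columns station_id, lat, lon, aod, residual.  Days with
    fewer than ``k_min`` points return the "global" pooled-OLS fallback.
    """
    if len(day) < k_min:
        return _global_fallback(day.sort_values("station_id", kind="stable").reset_index(drop=True),
                                day["date"].iloc[0] if "date" in day else None)
    return _fit_prepared(_prepare_day(day), k)


def _fit_prepared(prep: dict, k: int) -> GWRDayFit:
    date = prep["date"]
    lat, lon, x, y, sid, d = prep["lat"], prep["lon"], prep["x"], prep["y"], prep["sid"], prep["dist"]
    n = x.size
    k = min(k, n - 1)
    # vectorized over calibration points: one weight row per kernel center;
    # the ranking that sets the bandwidth excludes the center itself
    d_rank = np.where(d > 0.0, d, np.inf)
    hvec = np.partition(d_rank, k - 1, axis=1)[:, k - 1] * (1.0 + BANDWIDTH_INFLATION)
    u = d / hvec[:, None]
    W = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
    sw = W.sum(axis=1)
    swx = W @ x
    swy = W @ y
    swxx = W @ (x * x)
    swxy = W @ (x * y)
    det = sw * swxx - swx * swx
    var_x = swxx / sw - (swx / sw) ** 2
    singular = (var_x < SINGULAR_TOL) | (det <= 0)
    safe_det = np.where(singular, 1.0, det)
    b1 = np.where(singular, 0.0, (sw * swxy - swx * swy) / safe_det)
    b0 = np.where(singular, swy / sw, (swy - b1 * swx) / sw)
    # hat value at point i: w_ii * x_i'(X'WX)^{-1}x_i   (w_ii = 1 at d=0)
    wii = np.diagonal(W)
    hat_ok = wii * (swxx - 2.0 * swx * x + sw * x**2) / safe_det
    hat = np.where(singular, wii / sw, hat_ok)
    fitted = b0 + b1 * x
    resid = y - fitted
    rss = float(np.sum(resid**2))
    tr_s = float(np.sum(hat))
    aicc = _aicc(n, rss, tr_s)
    return GWRDayFit(date, sid, lat, lon, x, y, k=int(k), bandwidth=hvec, b0=b0, b1=b1,
                     singular=singular, hat=hat, fitted=fitted, trace_s=tr_s, rss=rss, aicc=aicc)


def _aicc(n: int, rss: float, tr_s: float) -> float:
    denom = n - 2.0 - tr_s
    if denom <= 0:
        return np.inf
    sigma = np.sqrt(max(rss, 1e-300) / n)
    return 2.0 * n * np.log(sigma) + n * np.log(2.0 * np.pi) + n * (n + tr_s) / denom


def select_bandwidth(day: pd.DataFrame, k_range: tuple[int, int] | None = None,
                     k_min: int = K_MIN, exhaustive_limit: int = 50) -> tuple[int, pd.DataFrame]:
    """Choose the neighbor count k* minimizing AICc for one day.

    Exhaustive search for n <= ``exhaustive_limit`` calibration points,
    golden-section otherwise; ties go to the smaller k.  Returns
    ``(k_star, curve)`` with the evaluated AICc values.  Raises if no k in
    the range yields a finite AICc.
    """
    n = len(day)
    lo, hi = k_range if k_range is not None else (k_min, n)
    lo = max(lo, 2)
    hi = min(hi, n - 1)
    if lo > hi:
        raise ValueError("empty k range")
    prep = _prepare_day(day)
    cache: dict[int, float] = {}

    def crit(k: int) -> float:
        if k not in cache:
            cache[k] = _fit_prepared(prep, k).aicc
        return cache[k]

    if n <= exhaustive_limit:
        for k in range(lo, hi + 1):
            crit(k)
    else:
        golden_section_k(crit, lo, hi)
    curve = pd.DataFrame(sorted(cache.items()), columns=["k", "aicc"])
    finite = curve[np.isfinite(curve["aicc"])]
    if finite.empty:
        raise ValueError("AICc undefined (n - 2 - tr(S) <= 0) for every k in range")
    best = finite.loc[finite["aicc"].idxmin()]
    # tie-break: smallest k within 1e-12 of the minimum
    ties = finite[finite["aicc"] <= best["aicc"] + 1e-12]
    return int(ties["k"].min()), curve


def golden_section_k(crit, lo: int, hi: int) -> int:
    """Golden-section search over integer k; evaluates all once |bracket|<=8.

    Finds the argmin exactly whenever the criterion is unimodal in k; on
    non-unimodal curves (possible for noisy small-n days) it returns a local
    minimizer, which is why the exhaustive search is the default at small n.
    """
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    while b - a > 8:
        c = int(round(b - invphi * (b - a)))
        d = int(round(a + invphi * (b - a)))
        if c == d:
            d += 1
        if crit(c) < crit(d):
            b = d
        else:
            a = c
    vals = {k: crit(k) for k in range(a, b + 1)}
    return min(vals, key=lambda k: (vals[k], k))


def _local_coeffs_at(fit: GWRDayFit, lat: np.ndarray, lon: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Kernel-recentered local (b0, b1) at arbitrary points, vectorized."""
    x = fit.aod
    y = fit.residual
    k = min(fit.k, x.size - 1)
    d = haversine_km(lat[:, None], lon[:, None], fit.lat[None, :], fit.lon[None, :])
    d_rank = np.where(d > 0.0, d, np.inf)
    kth = np.partition(d_rank, k - 1, axis=1)[:, k - 1] * (1.0 + BANDWIDTH_INFLATION)
    u = d / kth[:, None]
    w = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
    sw = w.sum(axis=1)
    swx = w @ x
    swy = w @ y
    swxx = w @ (x * x)
    swxy = w @ (x * y)
    det = sw * swxx - swx * swx
    var_x = swxx / sw - (swx / sw) ** 2
    ok = (var_x >= SINGULAR_TOL) & (det > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        b1 = np.where(ok, (sw * swxy - swx * swy) / np.where(det == 0, 1.0, det), 0.0)
        b0 = np.where(ok, (swy - b1 * swx) / sw, swy / sw)
    return b0, b1


def predict_gwr(fit: GWRDayFit, aod: DailyField) -> DailyField:
    """Residual surface by kernel re-centering at every grid cell.

    For "global" fallback days the pooled line is applied everywhere.  The
    local solve is fully vectorized over cells.
    """
    grid = aod.grid
    if fit.status == "global":
        vals = fit.global_b0 + fit.global_b1 * aod.values
        return DailyField(grid, aod.date, np.where(aod.mask, 0.0, vals), aod.mask.copy())
    glat, glon = grid.mesh()
    b0, b1 = _local_coeffs_at(fit, glat.ravel(), glon.ravel())
    vals = (b0 + b1 * aod.values.ravel()).reshape(grid.shape)
    vals = np.where(aod.mask, 0.0, vals)
    return DailyField(grid, aod.date, vals, aod.mask.copy())


def fit_gwr_all_days(residuals: pd.DataFrame, k_min: int = K_MIN,
                     k_range: tuple[int, int] | None = None) -> dict:
    """Select k* and fit the local model for every day of a residual table."""
    fits = {}
    for date, day in residuals.groupby("date", sort=True):
        n = len(day)
        if n < k_min:
            fits[date] = _global_fallback(day.reset_index(drop=True), date)
            continue
        prep = _prepare_day(day)
        lo, hi = (max(k_min, 2), n - 1) if k_range is None else (max(k_range[0], 2), min(k_range[1], n - 1))
        cands = [(_fit_prepared(prep, k), k) for k in range(lo, hi + 1)] if n <= 50 else None
        if cands is not None:
            finite = [(f.aicc, k, f) for f, k in cands if np.isfinite(f.aicc)]
            if not finite:
                fits[date] = _global_fallback(day.reset_index(drop=True), date)
                continue
            finite.sort(key=lambda t: (t[0], t[1]))
            fits[date] = finite[0][2]
        else:
            try:
                k_star, _ = select_bandwidth(day, k_range=k_range, k_min=k_min)
            except ValueError:
                fits[date] = _global_fallback(day.reset_index(drop=True), date)
                continue
            fits[date] = _fit_prepared(prep, k_star)
    return fits


def day_summaries(fits: dict) -> pd.DataFrame:
    rows = [(d, f.n, f.k, f.aicc, f.trace_s, f.status) for d, f in sorted(fits.items())]
    return pd.DataFrame(rows, columns=["date", "n", "k", "aicc", "trace_s", "status"])


def predict_gwr_at_points(fit: GWRDayFit, lat: np.ndarray, lon: np.ndarray, aod: np.ndarray) -> np.ndarray:
    """Kernel-recentered prediction at arbitrary points (CV held-out rows)."""
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    aod = np.atleast_1d(np.asarray(aod, dtype=float))
    if fit.status == "global":
        return fit.global_b0 + fit.global_b1 * aod
    b0, b1 = _local_coeffs_at(fit, lat, lon)
    return b0 + b1 * aod


def assemble_final(stage2: FieldStack, residual_surfaces: FieldStack, floor: float = 0.5) -> FieldStack:
    """Final PM2.5 = stage-2 prediction + GWR residual surface, floored."""
    vals = stage2.values + residual_surfaces.values
    mask = stage2.mask | residual_surfaces.mask
    vals = np.where(mask, 0.0, np.maximum(vals, floor))
    return FieldStack(stage2.grid, stage2.dates, vals, mask)


def seasonal_means(stack: FieldStack) -> dict[str, np.ndarray]:
    """Annual and IMD-season mean maps (winter JF, pre-monsoon MAM,
    monsoon JJAS, post-monsoon OND)."""
    from .grid import SEASONS, season_of
    out = {"annual": np.nanmean(stack.filled_nan, axis=0)}
    labels = np.array([season_of(d) for d in stack.dates])
    for s in SEASONS:
        sel = labels == s
        if sel.any():
            out[s] = np.nanmean(stack.filled_nan[sel], axis=0)
    return out
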