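"""Regridding, time averaging, screening and collocation.

Turns heterogeneous inputs (fine satellite fields, coarse reanalysis
fields, hourly stacks, road segments, fine land-class maps, monitor
records) into a single station-day analysis table on the 0.03 deg grid.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .grid import DailyField, FieldStack, GridSpec, haversine_km

__all__ = [
    "regrid_average", "regrid_bilinear", "overpass_window_mean",
    "road_density", "landcover_counts", "screen_extremes", "collocate",
]


def regrid_average(fine: DailyField, target: GridSpec) -> DailyField:
    """Average fine-cell values whose centers fall in each target cell.

    Membership is half-open, so every fine center contributes to at most one
    target cell.  A target cell with no contributing values is missing.
    """
    if fine.grid.cell >= target.cell:
        raise ValueError("fine grid must be finer than the target grid")
    flat, fj = target.cell_index(*[a.ravel() for a in fine.grid.mesh()])
    vals = fine.values.ravel()
    good = (~fine.mask.ravel()) & (flat >= 0)
    if not good.any():
        warnings.warn("no fine values fall inside the target grid")
        out = np.zeros(target.shape)
        return DailyField(target, fine.date, out, np.ones(target.shape, dtype=bool))
    idx = flat[good] * target.n_lon + fj[good]
    sums = np.bincount(idx, weights=vals[good], minlength=target.n_lat * target.n_lon)
    counts = np.bincount(idx, minlength=target.n_lat * target.n_lon)
    mask = counts == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[mask] = 0.0
    return DailyField(target, fine.date, out.reshape(target.shape), mask.reshape(target.shape))


def regrid_bilinear(coarse: DailyField, target: GridSpec) -> DailyField:
    """Bilinear interpolation of a complete coarse field to target centers.

    Target centers outside the coarse hull are clamped to the nearest edge
    coordinate before interpolating (edge-value extrapolation).
    """
    if coarse.grid.n_lat < 2 or coarse.grid.n_lon < 2:
        raise ValueError("coarse grid must be at least 2x2")
    if coarse.mask.any():
        raise ValueError("coarse field must be complete")
    interp = RegularGridInterpolator((coarse.grid.lats, coarse.grid.lons), coarse.values,
                                     method="linear", bounds_error=False)
    glat, glon = target.mesh()
    qlat = np.clip(glat, coarse.grid.lats[0], coarse.grid.lats[-1])
    qlon = np.clip(glon, coarse.grid.lons[0], coarse.grid.lons[-1])
    out = interp(np.column_stack([qlat.ravel(), qlon.ravel()])).reshape(target.shape)
    return DailyField(target, coarse.date, out, np.zeros(target.shape, dtype=bool))


def overpass_window_mean(hourly: FieldStack, window: tuple[int, int], hours: list[int] | None = None) -> DailyField:
    """Per-cell mean over an inclusive hour window (e.g. 05-08 UTC).

    ``hourly`` is a stack whose slices correspond to ``hours`` (defaults to
    0..len-1).  Missing hours are skipped; a cell is missing only if every
    hour in the window is missing there.
    """
    lo, hi = window
    if hi < lo:
        raise ValueError("empty hour window")
    hours = hours if hours is not None else list(range(len(hourly)))
    sel = [i for i, h in enumerate(hours) if lo <= h <= hi]
    if not sel:
        raise ValueError("window covers no provided hours")
    vals = hourly.filled_nan[sel]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        out = np.nanmean(vals, axis=0)
    mask = ~np.isfinite(out)
    out[mask] = 0.0
    return DailyField(hourly.grid, hourly.dates[sel[0]], out, mask)


def _split_segment(p1: np.ndarray, p2: np.ndarray, grid: GridSpec) -> list[tuple[int, int, np.ndarray, np.ndarray]]:
    """Split a (lat,lon) segment at every grid-line crossing.

    Returns [(i, j, a, b)] sub-segments, each wholly inside cell (i, j);
    pieces outside the grid are dropped.
    """
    ts = [0.0, 1.0]
    for axis, (origin, n_cells) in enumerate([(grid.lat0, grid.n_lat), (grid.lon0, grid.n_lon)]):
        d = p2[axis] - p1[axis]
        if d == 0.0:
            continue
        edges = origin - grid.cell / 2.0 + grid.cell * np.arange(n_cells + 1)
        t = (edges - p1[axis]) / d
        ts.extend(t[(t > 0.0) & (t < 1.0)].tolist())
    ts = np.unique(np.asarray(ts))
    pieces = []
    for a, b in zip(ts[:-1], ts[1:]):
        pa = p1 + a * (p2 - p1)
        pb = p1 + b * (p2 - p1)
        mid = 0.5 * (pa + pb)
        i, j = grid.cell_index(mid[0], mid[1])
        if i >= 0:
            pieces.append((int(i), int(j), pa, pb))
    return pieces


def road_density(segments: pd.DataFrame, grid: GridSpec) -> np.ndarray:
    """Great-circle road length per cell divided by spherical cell area.

    ``segments`` has columns lat1, lon1, lat2, lon2.  Zero-length segments
    are ignored (their count is reported via a warning).  Returns km/km2.
    """
    length = np.zeros(grid.shape)
    n_zero = 0
    for row in segments.itertuples(index=False):
        p1 = np.array([row.lat1, row.lon1], dtype=float)
        p2 = np.array([row.lat2, row.lon2], dtype=float)
        if np.all(p1 == p2):
            n_zero += 1
            continue
        for i, j, a, b in _split_segment(p1, p2, grid):
            length[i, j] += haversine_km(a[0], a[1], b[0], b[1])
    if n_zero:
        warnings.warn(f"ignored {n_zero} zero-length road segments")
    return length / grid.cell_area_km2()


def landcover_counts(class_grid: np.ndarray, class_gridspec: GridSpec, target: GridSpec,
                     classes: dict[str, int]) -> dict[str, np.ndarray]:
    """Count fine land-class cells of each requested class per target cell."""
    if class_gridspec.cell >= target.cell:
        raise ValueError("class grid must be finer than the target grid")
    known = set(np.unique(class_grid).tolist())
    for name, label in classes.items():
        if label not in known:
            raise ValueError(f"unknown class label {label} ({name}) not present in class grid")
    fi, fj = target.cell_index(*[a.ravel() for a in class_gridspec.mesh()])
    inside = fi >= 0
    idx = fi[inside] * target.n_lon + fj[inside]
    labels = class_grid.ravel()[inside]
    out = {}
    for name, label in classes.items():
        counts = np.bincount(idx[labels == label], minlength=target.n_lat * target.n_lon)
        out[name] = counts.reshape(target.shape).astype(np.int64)
    return out


def screen_extremes(monitors: pd.DataFrame, quantile: float = 0.999,
                    fixed_threshold: float | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop records strictly above the global empirical PM2.5 quantile.

    The threshold is the type-7 (linear-interpolation) quantile of the whole
    table, matching a single global screen.  Pass ``fixed_threshold`` to
    reuse a previously computed threshold (makes a second pass a no-op).
    Returns ``(kept, removed)``.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    if len(monitors) < 10:
        raise ValueError("need at least 10 records to screen")
    thresh = fixed_threshold if fixed_threshold is not None else float(
        np.quantile(monitors["pm25"].to_numpy(), quantile, method="linear"))
    above = monitors["pm25"] > thresh
    kept = monitors.loc[~above].copy()
    removed = monitors.loc[above].copy()
    kept.attrs["screen_threshold"] = thresh
    return kept, removed


def collocate(monitors: pd.DataFrame, final_aod: FieldStack, provenance: FieldStack | None,
              met: dict[str, FieldStack], static: dict[str, np.ndarray]) -> pd.DataFrame:
    """Build the station-day analysis table.

    One row per monitor record with the host-cell AOD (imputed final AOD),
    meteorology and static covariates.  Rows without PM2.5 are dropped; rows
    whose AOD is missing are kept but flagged ``aod_provenance='missing'``
    (they only feed the missing-AOD evaluation, never model fitting).
    """
    grid = final_aod.grid
    ci, cj = grid.cell_index(monitors["lat"].to_numpy(), monitors["lon"].to_numpy())
    if np.any(ci < 0):
        bad = monitors.loc[ci < 0, "station_id"].unique().tolist()
        raise ValueError(f"stations outside the grid: {bad}")
    date_idx = {d: t for t, d in enumerate(final_aod.dates)}
    rows = monitors.copy()
    rows = rows[rows["pm25"].notna()].copy()
    t = rows["date"].map(date_idx)
    keep = t.notna()
    rows = rows[keep].copy()
    ti = t[keep].astype(int).to_numpy()
    ci, cj = grid.cell_index(rows["lat"].to_numpy(), rows["lon"].to_numpy())
    rows["cell_i"], rows["cell_j"] = ci, cj
    aod_missing = final_aod.mask[ti, ci, cj]
    rows["aod"] = np.where(aod_missing, np.nan, final_aod.values[ti, ci, cj])
    if provenance is not None:
        codes = provenance.values[ti, ci, cj].astype(int)
        names = np.array(["observed", "imputed", "fallback", "missing"])
        rows["aod_provenance"] = names[np.clip(codes, 0, 3)]
        rows.loc[aod_missing, "aod_provenance"] = "missing"
    else:
        rows["aod_provenance"] = np.where(aod_missing, "missing", "observed")
    for name, stack in met.items():
        rows[name] = stack.values[ti, ci, cj]
    for name, arr in static.items():
        rows[name] = np.asarray(arr, dtype=float)[ci, cj]
    return rows.reset_index(drop=True)
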