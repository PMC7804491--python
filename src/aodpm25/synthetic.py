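"""Synthetic study-domain generator.

Emulates, from a known ground truth, every input the estimation pipeline
consumes: a complete "reanalysis" AOD field, a gappy "satellite" AOD field
linked to it cell-wise by ``sat = alpha_s + beta_s * rean + noise``, complete
daily meteorology with seasonal cycles, static land-cover counts, roads,
districts, a monitor network with occasional extreme outliers, and
district-level population / baseline-mortality tables.

The generative PM2.5 model mirrors the estimation model exactly: a linear
model in AOD, temperature, RH, wind, pressure and land-cover counts whose
intercept and meteorology/AOD slopes carry day-level Gaussian random effects,
plus a spatially varying residual AOD slope ``b1(s)`` and a residual split
into a spatially smooth day-specific field (regional events the day random
effects cannot absorb) and i.i.d. Gaussian noise.  With every noise term
switched off the generated data satisfy the three model stages exactly,
which is what the exact-recovery tests rely on.

All spatial structure is built from low-order harmonic surfaces, so fields
are smooth, cheap and fully reproducible from the configured seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from datetime import date as Date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .grid import FieldStack, GridSpec, season_of

__all__ = [
    "MetVarConfig", "MetConfig", "TruthConfig", "AODPair", "StaticLayers",
    "FixtureBundle", "simulate_meteorology", "simulate_aod_pair",
    "simulate_truth_pm25", "sample_monitors", "simulate_static_layers",
    "simulate_fixture", "write_fixture", "read_fixture", "default_dates",
]

FILL_VALUE = -9999.0

# Ordering of the day-random-effect terms: intercept then the five
# daily-varying covariate slopes.
RANDOM_TERMS = ("intercept", "aod", "temp", "rh", "wind", "pres")


def default_dates(year: int = 2018, n_days: int = 365) -> list[Date]:
    start = Date(year, 1, 1)
    return [start + timedelta(days=i) for i in range(n_days)]


def _harmonic_surface(grid: GridSpec, rng: np.random.Generator, n_modes: int = 4,
                      freq_range: tuple[float, float] = (0.4, 2.0)) -> np.ndarray:
    """Smooth zero-mean, unit-sd random surface from low-order harmonics."""
    y = np.linspace(0.0, 1.0, grid.n_lat)[:, None]
    x = np.linspace(0.0, 1.0, grid.n_lon)[None, :]
    out = np.zeros(grid.shape)
    for _ in range(n_modes):
        fy, fx = rng.uniform(*freq_range, size=2)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        amp = rng.normal(0.0, 1.0)
        out += amp * np.cos(2.0 * np.pi * (fy * y + fx * x) + phase)
    out -= out.mean()
    sd = out.std()
    if sd > 0:
        out /= sd
    return out


@dataclass(frozen=True)
class MetVarConfig:
    """Mean plus seasonal/spatial/weather variability of one variable.

    ``seasonal_amplitude`` multiplies a cosine annual cycle peaking at
    ``peak_doy``; ``spatial_amplitude`` multiplies a static smooth surface;
    ``weather_amplitude`` multiplies a smooth spatial field that changes
    day to day (synoptic weather).  Setting all three to zero yields a
    field constant at ``mean``.
    """

    mean: float
    seasonal_amplitude: float = 0.0
    spatial_amplitude: float = 0.0
    weather_amplitude: float = 0.0
    peak_doy: int = 135
    lo: float = -np.inf
    hi: float = np.inf


@dataclass(frozen=True)
class MetConfig:
    temp: MetVarConfig = MetVarConfig(25.0, 6.0, 2.0, 1.5, peak_doy=135)  # degC
    rh: MetVarConfig = MetVarConfig(0.55, 0.22, 0.06, 0.08, peak_doy=200, lo=0.0, hi=1.0)  # fraction
    u10: MetVarConfig = MetVarConfig(0.5, 1.0, 0.6, 1.0, peak_doy=170)  # m/s
    v10: MetVarConfig = MetVarConfig(1.0, 1.2, 0.6, 1.0, peak_doy=30)  # m/s
    pres: MetVarConfig = MetVarConfig(100000.0, 400.0, 900.0, 300.0, peak_doy=15, lo=1.0)  # Pa
    pblh: MetVarConfig = MetVarConfig(900.0, 350.0, 150.0, 200.0, peak_doy=130, lo=50.0)  # m


@dataclass(frozen=True)
class TruthConfig:
    """Ground-truth parameters of the synthetic study domain.

    The fixed effects ``a0..a7`` default to the fitted values of the model
    this package implements (intercept; AOD; temperature; RH; wind; surface
    pressure; urban count; grassland count).  ``re_sd`` are the day-level
    random-effect standard deviations for (intercept, AOD, temp, RH, wind,
    pressure); the random-effect covariance is diagonal.  ``b1_amplitude``
    scales the spatially varying residual AOD-PM2.5 slope that the GWR stage
    exists to recover.
    """

    # stage-1 link: satellite = alpha_s + beta_s * reanalysis + noise
    alpha_mean: float = 0.05
    alpha_spatial_amp: float = 0.03
    beta_mean: float = 1.15
    beta_spatial_amp: float = 0.10
    link_noise_sd: float = 0.11
    # reanalysis AOD (log-space structure; always positive, gap-free)
    rean_log_base: float = -1.05
    rean_spatial_amp: float = 0.25
    rean_daily_sd: float = 0.30
    rean_spatiotemporal_sd: float = 0.15
    # missingness
    gap_fraction: dict = dc_field(default_factory=lambda: {
        "winter": 0.25, "pre-monsoon": 0.30, "monsoon": 0.65, "post-monsoon": 0.35,
    })
    water_fraction: float = 0.02
    # stage-2/3 generative model
    fixed_effects: tuple = (-823.031, 34.833, -1.104, -23.502, -1.178, 0.009, 0.100, 0.796)
    re_sd: tuple = (5.0, 10.0, 0.5, 8.0, 0.5, 2e-5)
    sigma_eps: float = 7.0           # i.i.d. residual component, ug/m3
    eps_spatial_sd: float = 7.0      # spatially smooth day-specific residual, ug/m3
    b1_amplitude: float = 28.0
    wind_var: str = "v10"
    pm25_floor: float = 0.5
    # monitors
    n_stations: int = 12
    monitor_noise_sd: float = 5.0
    outlier_rate: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if self.sigma_eps < 0:
            raise ValueError("sigma_eps must be non-negative")
        if any(s < 0 for s in self.re_sd):
            raise ValueError("random-effect sds must be non-negative")
        for season, f in self.gap_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"gap fraction for {season} outside [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), int(stream)]))


def simulate_meteorology(grid: GridSpec, dates: list[Date], seed: int, config: MetConfig | None = None) -> dict[str, FieldStack]:
    """Complete (gap-free) daily meteorology fields.

    Each variable is mean + seasonal cosine + static smooth surface +
    day-varying smooth weather anomalies, clipped to its physical range
    (RH to [0, 1]).
    """
    if not dates:
        raise ValueError("date list must be non-empty")
    config = config or MetConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 90]))
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)
    out: dict[str, FieldStack] = {}
    n_modes = 3
    for name in ("temp", "rh", "u10", "v10", "pres", "pblh"):
        cfg: MetVarConfig = getattr(config, name)
        surface = _harmonic_surface(grid, rng)
        seasonal = np.cos(2.0 * np.pi * (doy - cfg.peak_doy) / 365.25)
        vals = (cfg.mean
                + cfg.seasonal_amplitude * seasonal[:, None, None]
                + cfg.spatial_amplitude * surface[None, :, :])
        if cfg.weather_amplitude != 0.0:
            # day-varying smooth spatial anomalies (synoptic weather)
            modes = np.stack([_harmonic_surface(grid, rng) for _ in range(n_modes)])
            coeff = rng.normal(0.0, cfg.weather_amplitude / np.sqrt(n_modes), size=(len(dates), n_modes))
            vals = vals + np.einsum("tk,kij->tij", coeff, modes)
        vals = np.clip(vals, cfg.lo, cfg.hi)
        out[name] = FieldStack(grid, dates, vals, np.zeros(vals.shape, dtype=bool))
    return out


def _water_mask(grid: GridSpec, rng: np.random.Generator, fraction: float) -> np.ndarray:
    """One contiguous elliptical blob of permanently missing cells."""
    n_target = int(round(fraction * grid.n_lat * grid.n_lon))
    mask = np.zeros(grid.shape, dtype=bool)
    if n_target == 0:
        return mask
    ci = rng.uniform(0.25, 0.75) * grid.n_lat
    cj = rng.uniform(0.25, 0.75) * grid.n_lon
    ii, jj = np.meshgrid(np.arange(grid.n_lat), np.arange(grid.n_lon), indexing="ij")
    d2 = ((ii - ci) / grid.n_lat) ** 2 + ((jj - cj) / (0.7 * grid.n_lon)) ** 2
    thresh = np.partition(d2.ravel(), n_target - 1)[n_target - 1]
    mask[d2 <= thresh] = True
    return mask


@dataclass
class AODPair:
    """Satellite/reanalysis AOD pair plus the generating truth."""

    satellite: FieldStack          # gappy
    reanalysis: FieldStack         # complete
    satellite_full: FieldStack     # satellite before masking (the "true" AOD)
    alpha: np.ndarray              # per-cell intercept of the link
    beta: np.ndarray               # per-cell slope of the link
    water_mask: np.ndarray
    n_clipped: int                 # negative satellite draws clipped to 0

    def __iter__(self):
        return iter((self.satellite, self.reanalysis))


def simulate_aod_pair(grid: GridSpec, dates: list[Date], truth: TruthConfig) -> AODPair:
    """Generate the linked AOD pair and apply seasonal + water masking."""
    if not dates:
        raise ValueError("date list must be non-empty")
    rng_link = truth.rng(1)
    rng_rean = truth.rng(2)
    rng_gap = truth.rng(3)

    alpha = truth.alpha_mean + truth.alpha_spatial_amp * _harmonic_surface(grid, rng_link)
    beta = truth.beta_mean + truth.beta_spatial_amp * _harmonic_surface(grid, rng_link)

    n_t = len(dates)
    base = truth.rean_log_base + truth.rean_spatial_amp * _harmonic_surface(grid, rng_rean)
    daily = rng_rean.normal(0.0, truth.rean_daily_sd, size=n_t)
    # spatio-temporal term: daily coefficients on a few fixed harmonic modes
    n_modes = 4
    modes = np.stack([_harmonic_surface(grid, rng_rean) for _ in range(n_modes)])
    coeff = rng_rean.normal(0.0, truth.rean_spatiotemporal_sd / np.sqrt(n_modes), size=(n_t, n_modes))
    log_rean = base[None] + daily[:, None, None] + np.einsum("tk,kij->tij", coeff, modes)
    rean_vals = np.exp(log_rean)
    reanalysis = FieldStack(grid, dates, rean_vals, np.zeros(rean_vals.shape, dtype=bool))

    sat_vals = alpha[None] + beta[None] * rean_vals
    if truth.link_noise_sd > 0:
        sat_vals = sat_vals + rng_link.normal(0.0, truth.link_noise_sd, size=sat_vals.shape)
    n_clipped = int(np.sum(sat_vals < 0.0))
    sat_vals = np.maximum(sat_vals, 0.0)
    satellite_full = FieldStack(grid, dates, sat_vals.copy(), np.zeros(sat_vals.shape, dtype=bool))

    water = _water_mask(grid, truth.rng(4), truth.water_fraction)
    gap_p = np.array([truth.gap_fraction[season_of(d)] for d in dates])
    gaps = rng_gap.random(sat_vals.shape) < gap_p[:, None, None]
    mask = gaps | water[None, :, :]
    satellite = FieldStack(grid, dates, sat_vals.copy(), mask)
    return AODPair(satellite, reanalysis, satellite_full, alpha, beta, water, n_clipped)


def simulate_truth_pm25(fields: dict[str, FieldStack], aod_true: FieldStack, truth: TruthConfig,
                        urban: np.ndarray, grass: np.ndarray):
    """Ground-truth PM2.5 from the generative linear model.

    Returns ``(stack, report)`` where ``report`` holds the drawn day random
    effects (original units), the residual-slope field ``b1`` and the
    fraction of cell-days floored at ``truth.pm25_floor``.
    """
    needed = ("temp", "rh", truth.wind_var, "pres")
    for name in needed:
        if name not in fields:
            raise ValueError(f"missing covariate field: {name}")
    grid = aod_true.grid
    dates = aod_true.dates
    n_t = len(dates)
    rng = truth.rng(5)
    a = np.asarray(truth.fixed_effects, dtype=float)
    re = rng.normal(0.0, 1.0, size=(n_t, 6)) * np.asarray(truth.re_sd)
    # the residual slope varies at regional scale (a fraction of a cycle
    # across the domain) so a sparse monitor network can resolve it
    b1 = truth.b1_amplitude * _harmonic_surface(grid, truth.rng(6), n_modes=2, freq_range=(0.25, 0.6))

    aod = aod_true.values
    temp = fields["temp"].values
    rh = fields["rh"].values
    wind = fields[truth.wind_var].values
    pres = fields["pres"].values

    pm = ((a[0] + re[:, 0, None, None])
          + (a[1] + re[:, 1, None, None]) * aod
          + (a[2] + re[:, 2, None, None]) * temp
          + (a[3] + re[:, 3, None, None]) * rh
          + (a[4] + re[:, 4, None, None]) * wind
          + (a[5] + re[:, 5, None, None]) * pres
          + a[6] * urban[None]
          + a[7] * grass[None]
          + b1[None] * aod)
    # residual: a spatially smooth day-specific field (regional events the
    # day random effects cannot absorb) plus i.i.d. noise
    if truth.eps_spatial_sd > 0:
        n_modes = 3
        rng_eps = truth.rng(9)
        modes = np.stack([_harmonic_surface(grid, rng_eps, n_modes=2, freq_range=(0.25, 0.8))
                          for _ in range(n_modes)])
        coeff = rng_eps.normal(0.0, truth.eps_spatial_sd / np.sqrt(n_modes), size=(n_t, n_modes))
        pm = pm + np.einsum("tk,kij->tij", coeff, modes)
    if truth.sigma_eps > 0:
        pm = pm + rng.normal(0.0, truth.sigma_eps, size=pm.shape)
    floored = pm < truth.pm25_floor
    pm = np.maximum(pm, truth.pm25_floor)
    report = {
        "random_effects": pd.DataFrame(re, index=pd.Index(dates, name="date"), columns=list(RANDOM_TERMS)),
        "b1": b1,
        "floor_rate": float(floored.mean()),
    }
    return FieldStack(grid, dates, pm, np.zeros(pm.shape, dtype=bool)), report


def sample_monitors(truth_pm25: FieldStack, n_stations: int, noise_sd: float,
                    outlier_rate: float, seed: int, exclude: np.ndarray | None = None,
                    weights: np.ndarray | None = None) -> pd.DataFrame:
    """Place monitors at distinct cells and observe truth plus noise.

    ``weights`` (e.g. population) bias the placement toward inhabited cells,
    emulating an urban regulatory network.  With probability
    ``outlier_rate`` an observation is replaced by an extreme value drawn
    uniformly in [500, 1000] ug/m3, exercising the 99.9th-percentile
    screening downstream.
    """
    grid = truth_pm25.grid
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    allowed = np.ones(grid.shape, dtype=bool)
    if exclude is not None:
        allowed &= ~exclude
    flat = np.flatnonzero(allowed.ravel())
    if n_stations > flat.size:
        raise ValueError(f"n_stations={n_stations} exceeds {flat.size} available cells")
    p = None
    if weights is not None:
        w = np.asarray(weights, dtype=float).ravel()[flat]
        if w.sum() > 0:
            p = w / w.sum()
    cells = rng.choice(flat, size=n_stations, replace=False, p=p)
    ci, cj = np.unravel_index(cells, grid.shape)
    lats = grid.lats[ci]
    lons = grid.lons[cj]
    rows = []
    for s in range(n_stations):
        sid = f"S{s + 1:02d}"
        obs = truth_pm25.values[:, ci[s], cj[s]].copy()
        if noise_sd > 0:
            obs = obs + rng.normal(0.0, noise_sd, size=obs.shape)
        if outlier_rate > 0:
            hit = rng.random(obs.shape) < outlier_rate
            obs[hit] = rng.uniform(500.0, 1000.0, size=int(hit.sum()))
        for t, d in enumerate(truth_pm25.dates):
            rows.append((sid, float(lats[s]), float(lons[s]), d, float(obs[t]), int(ci[s]), int(cj[s])))
    return pd.DataFrame(rows, columns=["station_id", "lat", "lon", "date", "pm25", "cell_i", "cell_j"])


AGE_GROUPS = ("25-34", "35-44", "45-54", "55-64", "65-74", "75+")
AGE_SHARES = (0.28, 0.24, 0.20, 0.14, 0.09, 0.05)
DISEASES = ("IHD", "stroke", "COPD", "LNC")
# Baseline mortality per person per year (central), scaled up with age.
_BM_BASE = {"IHD": 1.6e-3, "stroke": 1.1e-3, "COPD": 0.9e-3, "LNC": 1.2e-4}
_BM_AGE_FACTOR = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)


@dataclass
class StaticLayers:
    urban: np.ndarray          # integer fine-cell counts per cell
    grass: np.ndarray
    crop: np.ndarray
    class_grid: np.ndarray     # fine land-class labels (0 other, 1 urban, 2 grass, 3 crop)
    class_gridspec: GridSpec
    roads: pd.DataFrame        # columns lat1, lon1, lat2, lon2
    districts: np.ndarray      # integer district label per cell
    population: np.ndarray     # persons (age 25+) per cell
    health: pd.DataFrame       # district, age_group, disease, pop, bm_lo, bm_mid, bm_hi


def simulate_static_layers(grid: GridSpec, seed: int, fine_factor: int = 5,
                           district_shape: tuple[int, int] = (4, 5)) -> StaticLayers:
    """Land-cover counts, roads, districts, population and health tables.

    Land classes are simulated on a ``fine_factor``-times finer grid and
    counted per analysis cell.  Districts are rectangular blocks of cells;
    every cell belongs to exactly one district.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 8]))
    fine = GridSpec(
        lat0=grid.lat0 - grid.cell / 2.0 + grid.cell / (2.0 * fine_factor),
        lon0=grid.lon0 - grid.cell / 2.0 + grid.cell / (2.0 * fine_factor),
        n_lat=grid.n_lat * fine_factor, n_lon=grid.n_lon * fine_factor,
        cell=grid.cell / fine_factor,
    )
    # a few urban hotspots; grass/crop from smooth surfaces
    n_hot = 5
    hot_i = rng.uniform(0, fine.n_lat, n_hot)
    hot_j = rng.uniform(0, fine.n_lon, n_hot)
    ii, jj = np.meshgrid(np.arange(fine.n_lat), np.arange(fine.n_lon), indexing="ij")
    urban_p = np.zeros(fine.shape)
    for k in range(n_hot):
        d2 = ((ii - hot_i[k]) / fine.n_lat) ** 2 + ((jj - hot_j[k]) / fine.n_lon) ** 2
        urban_p += np.exp(-d2 / 0.002)
    urban_p = np.clip(urban_p, 0.0, 1.0) * 0.85
    # grass/crop: smooth regional propensity plus fine-scale patchiness, so
    # every analysis cell carries a varying (never identically zero) count
    g_score = 0.6 * _harmonic_surface(fine, rng) + rng.normal(0.0, 0.8, fine.shape)
    c_score = 0.6 * _harmonic_surface(fine, rng) + rng.normal(0.0, 0.8, fine.shape)
    u = rng.random(fine.shape)
    labels = np.zeros(fine.shape, dtype=np.int8)
    labels[u < urban_p] = 1
    remaining = labels == 0
    labels[remaining & (g_score > 0.85)] = 2
    remaining = labels == 0
    labels[remaining & (c_score > 0.35)] = 3

    def _count(cls: int) -> np.ndarray:
        m = (labels == cls).astype(np.int64)
        return m.reshape(grid.n_lat, fine_factor, grid.n_lon, fine_factor).sum(axis=(1, 3))

    urban, grass, crop = _count(1), _count(2), _count(3)

    # roads: hotspot-to-hotspot links plus a few random segments
    hot_lat = fine.lat0 + fine.cell * hot_i
    hot_lon = fine.lon0 + fine.cell * hot_j
    segs = []
    for a in range(n_hot):
        for b in range(a + 1, n_hot):
            segs.append((hot_lat[a], hot_lon[a], hot_lat[b], hot_lon[b]))
    for _ in range(8):
        la, lb = rng.uniform(grid.lats[0], grid.lats[-1], 2)
        oa, ob = rng.uniform(grid.lons[0], grid.lons[-1], 2)
        segs.append((la, oa, lb, ob))
    roads = pd.DataFrame(segs, columns=["lat1", "lon1", "lat2", "lon2"])

    # districts: rectangular blocks
    dr, dc = district_shape
    row_edges = np.linspace(0, grid.n_lat, dr + 1).astype(int)
    col_edges = np.linspace(0, grid.n_lon, dc + 1).astype(int)
    districts = np.zeros(grid.shape, dtype=np.int32)
    lab = 0
    for r in range(dr):
        for c in range(dc):
            districts[row_edges[r]:row_edges[r + 1], col_edges[c]:col_edges[c + 1]] = lab
            lab += 1

    # population: lognormal background plus mass near urban hotspots
    pop_surf = _harmonic_surface(grid, rng)
    urban_frac = urban / float(fine_factor**2)
    population = 400.0 * np.exp(0.5 * pop_surf) + 20000.0 * urban_frac
    population = np.round(population).astype(float)

    rows = []
    for d in range(dr * dc):
        pop_d = float(population[districts == d].sum())
        for age, share in zip(AGE_GROUPS, AGE_SHARES):
            for dis in DISEASES:
                mid = _BM_BASE[dis] * _BM_AGE_FACTOR[AGE_GROUPS.index(age)]
                mid *= float(rng.uniform(0.85, 1.15))
                lo, hi = 0.8 * mid, 1.25 * mid
                rows.append((d, age, dis, pop_d * share, lo, mid, hi))
    health = pd.DataFrame(rows, columns=["district", "age_group", "disease", "pop", "bm_lo", "bm_mid", "bm_hi"])
    return StaticLayers(urban, grass, crop, labels, fine, roads, districts, population, health)


@dataclass
class FixtureBundle:
    grid: GridSpec
    dates: list[Date]
    truth: TruthConfig
    met: dict[str, FieldStack]
    aod: AODPair
    pm25_truth: FieldStack
    pm25_report: dict
    monitors: pd.DataFrame
    static: StaticLayers


def simulate_fixture(grid: GridSpec | None = None, dates: list[Date] | None = None,
                     truth: TruthConfig | None = None, met_config: MetConfig | None = None) -> FixtureBundle:
    """Generate the full input bundle for one study period."""
    truth = truth or TruthConfig()
    grid = grid or GridSpec(lat0=21.3, lon0=74.4, n_lat=40, n_lon=50, cell=0.03)
    dates = dates or default_dates()
    met = simulate_meteorology(grid, dates, truth.seed, met_config)
    aod = simulate_aod_pair(grid, dates, truth)
    static = simulate_static_layers(grid, truth.seed)
    pm25, report = simulate_truth_pm25(met, aod.satellite_full, truth, static.urban.astype(float), static.grass.astype(float))
    monitors = sample_monitors(pm25, truth.n_stations, truth.monitor_noise_sd,
                               truth.outlier_rate, truth.seed, exclude=aod.water_mask,
                               weights=static.population)
    return FixtureBundle(grid, dates, truth, met, aod, pm25, report, monitors, static)


def _time_coord(dates: list[Date]) -> np.ndarray:
    epoch = Date(1970, 1, 1)
    return np.array([(d - epoch).days for d in dates], dtype=np.int32)


def write_fixture(bundle: FixtureBundle, directory) -> dict[str, Path]:
    """Write the bundle: NetCDF gridded fields, CSV tables, JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    grid = bundle.grid
    coords = {
        "time": ("time", _time_coord(bundle.dates), {"units": "days since 1970-01-01"}),
        "lat": ("lat", grid.lats, {"units": "degrees_north"}),
        "lon": ("lon", grid.lons, {"units": "degrees_east"}),
    }
    dyn_vars = {}
    sat = bundle.aod.satellite.values.copy()
    sat[bundle.aod.satellite.mask] = FILL_VALUE
    dyn_vars["aod_sat"] = (("time", "lat", "lon"), sat, {"_FillValue": FILL_VALUE})
    for name, stack in [("aod_rean", bundle.aod.reanalysis), ("pm25_truth", bundle.pm25_truth),
                        ("aod_sat_full", bundle.aod.satellite_full)] + [(k, v) for k, v in bundle.met.items()]:
        dyn_vars[name] = (("time", "lat", "lon"), stack.values)
    ds = xr.Dataset({k: xr.DataArray(v[1], dims=v[0], attrs=(v[2] if len(v) > 2 else {})) for k, v in dyn_vars.items()},
                    coords={k: xr.DataArray(v[1], dims=v[0], attrs=v[2]) for k, v in coords.items()})
    dyn_path = directory / "dynamic.nc"
    ds.to_netcdf(dyn_path, engine="scipy")

    st = bundle.static
    static_vars = {
        "urban": st.urban.astype(np.int32), "grass": st.grass.astype(np.int32),
        "crop": st.crop.astype(np.int32), "district": st.districts.astype(np.int32),
        "population": st.population,
        "alpha_true": bundle.aod.alpha, "beta_true": bundle.aod.beta,
        "b1_true": bundle.pm25_report["b1"],
        "water": bundle.aod.water_mask.astype(np.int8),
    }
    ds_s = xr.Dataset({k: (("lat", "lon"), v) for k, v in static_vars.items()},
                      coords={"lat": grid.lats, "lon": grid.lons})
    static_path = directory / "static.nc"
    ds_s.to_netcdf(static_path, engine="scipy")

    mon = bundle.monitors.copy()
    mon["date"] = mon["date"].map(lambda d: d.isoformat())
    mon_path = directory / "monitors.csv"
    mon.to_csv(mon_path, index=False)
    health_path = directory / "health.csv"
    st.health.to_csv(health_path, index=False)
    roads_path = directory / "roads.csv"
    st.roads.to_csv(roads_path, index=False)

    truth_dict = dataclasses.asdict(bundle.truth)
    manifest = {
        "seed": bundle.truth.seed,
        "truth_config": truth_dict,
        "grid": dataclasses.asdict(grid),
        "dates": [bundle.dates[0].isoformat(), bundle.dates[-1].isoformat()],
        "n_days": len(bundle.dates),
        "aod_negative_clipped": bundle.aod.n_clipped,
        "pm25_floor_rate": bundle.pm25_report["floor_rate"],
        "note": "link_noise_sd and all noise magnitudes are package defaults, not literature values",
    }
    man_path = directory / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {"dynamic": dyn_path, "static": static_path, "monitors": mon_path,
            "health": health_path, "roads": roads_path, "manifest": man_path}


def read_fixture(directory):
    """Read a written fixture back into stacks and tables.

    Returns a dict with the same keys the pipeline consumes; satellite AOD
    missingness is reconstructed from the declared fill value.
    """
    directory = Path(directory)
    with xr.open_dataset(directory / "dynamic.nc", engine="scipy", mask_and_scale=True) as ds:
        ds = ds.load()
    epoch = Date(1970, 1, 1)
    tvals = np.asarray(ds["time"].values)
    if np.issubdtype(tvals.dtype, np.datetime64):
        dates = [pd.Timestamp(t).date() for t in tvals]
    else:
        dates = [epoch + timedelta(days=int(t)) for t in tvals]
    lats = np.asarray(ds["lat"].values)
    lons = np.asarray(ds["lon"].values)
    cell = float(np.round(np.diff(lats).mean(), 10))
    grid = GridSpec(lat0=float(lats[0]), lon0=float(lons[0]), n_lat=lats.size, n_lon=lons.size, cell=cell)

    def _stack(name: str) -> FieldStack:
        vals = np.asarray(ds[name].values, dtype=float)
        mask = ~np.isfinite(vals) | (vals == FILL_VALUE)
        vals = np.where(mask, 0.0, vals)
        return FieldStack(grid, dates, vals, mask)

    out = {"grid": grid, "dates": dates}
    for name in ds.data_vars:
        out[name] = _stack(str(name))
    with xr.open_dataset(directory / "static.nc", engine="scipy") as ds_s:
        ds_s = ds_s.load()
    for name in ds_s.data_vars:
        out[name] = np.asarray(ds_s[name].values)
    mon = pd.read_csv(directory / "monitors.csv")
    mon["date"] = pd.to_datetime(mon["date"]).dt.date
    out["monitors"] = mon
    out["health"] = pd.read_csv(directory / "health.csv")
    out["roads"] = pd.read_csv(directory / "roads.csv")
    out["manifest"] = json.loads((directory / "manifest.json").read_text())
    return out
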