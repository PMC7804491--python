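"""End-to-end orchestration: simulate -> impute -> integrate -> LME -> GWR
-> cross-validate -> burden, with file handoffs and a run manifest.

Every stage writes its artifacts under the output directory; the manifest
records the seed, a hash of the resolved configuration and each stage's
status, so a run is reconstructible and (for a fixed seed) bit-reproducible.
All randomness flows from the single configured seed via named substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import health, integrate, stage1, stage2, stage3, validate
from .grid import FieldStack, GridSpec
from .synthetic import TruthConfig, default_dates, simulate_fixture, write_fixture, _time_coord

log = logging.getLogger("aodpm25")

STAGES = ("simulate", "impute", "integrate", "fit-lme", "fit-gwr", "cv", "burden")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    seed: int = 0
    outdir: str = "aodpm25_run"
    # domain
    lat0: float = 21.3
    lon0: float = 74.4
    n_lat: int = 40
    n_lon: int = 50
    cell: float = 0.03
    year: int = 2018
    n_days: int = 365
    # stage options
    n_min: int = 10              # stage-1 minimum paired days per cell
    k_min: int = 6               # stage-3 minimum calibration points per day
    wind_var: str = "v10"
    screen_quantile: float = 0.999
    cv_folds: int = 10
    cv_seed: int = 0
    run_stage3: bool = True
    write_daily_surfaces: bool = True
    ier_mode: str = "parametric"   # or "lookup"
    truth_overrides: dict = dc_field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        data = yaml.safe_load(path.read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def grid(self) -> GridSpec:
        return GridSpec(self.lat0, self.lon0, self.n_lat, self.n_lon, self.cell)

    def truth(self) -> TruthConfig:
        overrides = dict(self.truth_overrides)
        overrides.setdefault("seed", self.seed)
        overrides.setdefault("wind_var", self.wind_var)
        return TruthConfig(**overrides)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_stack(stack: FieldStack, path: Path, name: str, extra: dict | None = None) -> None:
    vals = stack.values.copy()
    vals[stack.mask] = synthetic_fill = -9999.0
    data = {name: xr.DataArray(vals, dims=("time", "lat", "lon"), attrs={"_FillValue": synthetic_fill})}
    for k, v in (extra or {}).items():
        data[k] = xr.DataArray(v, dims=("time", "lat", "lon"))
    ds = xr.Dataset(data, coords={
        "time": xr.DataArray(_time_coord(stack.dates), dims="time", attrs={"units": "days since 1970-01-01"}),
        "lat": stack.grid.lats, "lon": stack.grid.lons,
    })
    ds.to_netcdf(path, engine="scipy")


def _write_maps(maps: dict[str, np.ndarray], grid: GridSpec, path: Path) -> None:
    ds = xr.Dataset({k: (("lat", "lon"), np.asarray(v, dtype=float)) for k, v in maps.items()},
                    coords={"lat": grid.lats, "lon": grid.lons})
    ds.to_netcdf(path, engine="scipy")


def run_all(config: RunConfig) -> Path:
    """Execute every stage in order; returns the artifact directory.

    A stage failure halts the run with the stage name; completed artifacts
    are kept and the manifest records per-stage status.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    status: dict[str, str] = {s: "pending" for s in STAGES}
    manifest_path = out / "manifest.json"

    def _manifest():
        manifest = {"seed": config.seed, "config": dataclasses.asdict(config),
                    "config_hash": config.config_hash(), "stages": status}
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")

    current = "simulate"
    try:
        # ---- simulate -------------------------------------------------
        log.info("stage=simulate start")
        grid = config.grid()
        dates = default_dates(config.year, config.n_days)
        bundle = simulate_fixture(grid, dates, config.truth())
        write_fixture(bundle, out / "fixture")
        status["simulate"] = "ok"
        log.info("stage=simulate ok n_days=%d grid=%dx%d", len(dates), grid.n_lat, grid.n_lon)

        # ---- stage 1: imputation -------------------------------------
        current = "impute"
        coeffs = stage1.fit_gridwise_regression(bundle.aod.satellite, bundle.aod.reanalysis, n_min=config.n_min)
        final_aod, provenance = stage1.impute_aod(bundle.aod.satellite, bundle.aod.reanalysis, coeffs)
        diag = stage1.imputation_diagnostics(coeffs)
        _write_stack(final_aod, out / "final_aod.nc", "final_aod",
                     extra={"provenance": provenance.values.astype(np.int8)})
        _write_maps({"alpha": coeffs.alpha, "beta": coeffs.beta, "r2": coeffs.r2,
                     "p_value": coeffs.p_value, "n": coeffs.n.astype(float)}, grid, out / "imputation_coeffs.nc")
        pd.DataFrame([diag]).to_csv(out / "imputation_summary.csv", index=False)
        status["impute"] = "ok"
        log.info("stage=impute ok coverage=%.3f mean_r2=%.3f", diag["coverage"], diag["mean_r2"])

        # ---- integration ---------------------------------------------
        current = "integrate"
        road = integrate.road_density(bundle.static.roads, grid)
        static_covs = {"urban": bundle.static.urban, "grass": bundle.static.grass,
                       "crop": bundle.static.crop, "road_density": road}
        table = integrate.collocate(bundle.monitors, final_aod, provenance, bundle.met, static_covs)
        table, removed = integrate.screen_extremes(table, config.screen_quantile)
        table_out = table.copy()
        table_out["date"] = table_out["date"].map(lambda d: d.isoformat())
        table_out.to_csv(out / "analysis_table.csv", index=False)
        status["integrate"] = "ok"
        log.info("stage=integrate ok rows=%d screened=%d", len(table), len(removed))

        # ---- stage 2: LME --------------------------------------------
        current = "fit-lme"
        fixed = ("aod", "temp", "rh", config.wind_var, "pres", "urban", "grass")
        random = ("aod", "temp", "rh", config.wind_var, "pres")
        model_rows = table.dropna(subset=["aod"])
        fit = stage2.fit_lme(model_rows, fixed=fixed, random=random)
        fit.summary_table().to_csv(out / "lme_summary.csv", index=False)
        resid = stage2.station_residuals(fit, model_rows)
        resid_out = resid.copy()
        resid_out["date"] = resid_out["date"].map(lambda d: d.isoformat())
        resid_out.to_csv(out / "lme_residuals.csv", index=False)
        status["fit-lme"] = "ok"
        log.info("stage=fit-lme ok converged=%s sigma=%.2f", fit.converged, np.sqrt(fit.sigma2))

        # ---- stage 3: GWR + surfaces ---------------------------------
        current = "fit-gwr"
        covs_static = {"urban": bundle.static.urban.astype(float), "grass": bundle.static.grass.astype(float),
                       "crop": bundle.static.crop.astype(float), "road_density": road}
        surfaces2 = []
        for t, d in enumerate(dates):
            covs = {"aod": final_aod.values[t], **{k: bundle.met[k].values[t] for k in ("temp", "rh", "u10", "v10", "pres")},
                    **covs_static}
            pred, _ = stage2.predict_grid(fit, covs, d, grid)
            surfaces2.append(pred)
        stage2_stack = FieldStack.from_fields(surfaces2)
        if config.run_stage3:
            gwr_fits = stage3.fit_gwr_all_days(resid, k_min=config.k_min)
            stage3.day_summaries(gwr_fits).to_csv(out / "gwr_day_summaries.csv", index=False)
            resid_surfaces = FieldStack.from_fields(
                [stage3.predict_gwr(gwr_fits[d], final_aod.at(d)) for d in dates])
            final_stack = stage3.assemble_final(stage2_stack, resid_surfaces)
        else:
            final_stack = stage2_stack
        if config.write_daily_surfaces:
            _write_stack(final_stack, out / "pm25_daily.nc", "pm25")
        _write_maps(stage3.seasonal_means(final_stack), grid, out / "pm25_means.nc")
        status["fit-gwr"] = "ok" if config.run_stage3 else "skipped"
        log.info("stage=fit-gwr %s", status["fit-gwr"])

        # ---- cross-validation ----------------------------------------
        current = "cv"
        cv_table, cv_metrics = validate.cross_validate(
            table, k_folds=config.cv_folds, seed=config.cv_seed,
            fixed=fixed, random=random, k_min=config.k_min, run_stage3=config.run_stage3)
        cv_out = cv_table.copy()
        cv_out["date"] = cv_out["date"].map(lambda d: d.isoformat())
        cv_out.to_csv(out / "cv_predictions.csv", index=False)
        pd.DataFrame({k: v.as_dict() for k, v in cv_metrics.items()}).to_csv(out / "cv_metrics.csv")
        report = validate.stationwise_and_missing_day_eval(cv_table)
        report["stations"].to_csv(out / "cv_stations.csv", index=False)
        status["cv"] = "ok"
        msg = " ".join(f"{k}: r2={v.r2:.3f} rmse={v.rmse:.2f}" for k, v in cv_metrics.items())
        log.info("stage=cv ok %s", msg)

        # ---- burden ---------------------------------------------------
        current = "burden"
        annual = stage3.seasonal_means(final_stack)["annual"]
        district_cn = health.population_weighted_pm25(annual, bundle.static.population, bundle.static.districts)
        mortality = health.build_mortality_table(district_cn, bundle.static.health, year=config.year)
        mortality.to_csv(out / "mortality_table.csv", index=False)
        agg = health.aggregate_burden(mortality)
        agg["by_disease"].to_csv(out / "burden_by_disease.csv")
        agg["shares_pct"].rename("share_pct").to_csv(out / "burden_shares.csv")
        status["burden"] = "ok"
        log.info("stage=burden ok total=%.1f deaths", float(agg["overall"]["dm_mid"]))
    except Exception:
        status[current] = "failed"
        _manifest()
        log.exception("stage=%s failed; completed artifacts kept in %s", current, out)
        raise
    _manifest()
    return out
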