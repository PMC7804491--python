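# aodpm25

Estimating daily surface PM2.5 over a region from satellite aerosol optical
depth (AOD) is hard for two reasons: satellite AOD has large gaps (clouds,
monsoon, calibration), and the AOD–PM2.5 relationship varies in both time
and space. This package implements a three-stage statistical model that
addresses both, plus the downstream health-burden calculation, for
researchers in environmental epidemiology and air-quality modelling:

1. **Gap imputation** — per grid cell *s*, a yearly linear regression links
   the gappy satellite AOD to a complete reanalysis AOD:
   `AOD_final(s,t) = α_s + β_s · AOD_rean(s,t)` wherever the satellite value
   is missing.
2. **Linear mixed-effects model (LME)** — station-day PM2.5 on imputed AOD,
   meteorology and land use, with day-specific random intercept and slopes:
   `PM2.5(s,t) = (a0 + a0,t) + (a1 + a1,t)·AOD + … + a6·Urban + a7·Grass + ε`,
   `(a0,t … a5,t) ~ N(0, Σ)`, capturing the day-to-day variability of the
   AOD–PM2.5 relationship. Estimated by profiled REML (diagonal Σ).
3. **Geographically weighted regression (GWR)** — the LME residuals are
   regressed on AOD *locally* each day,
   `resid(s,t) = b0,s + b1,s·AOD(s,t) + ε¹`, with an adaptive bi-square
   kernel whose neighbor count k minimizes the small-sample-corrected AICc,
   capturing the spatial variability the LME cannot.

Final daily surfaces (stage-2 prediction + stage-3 residual surface) feed
district population-weighted exposures `Cn`, integrated exposure–response
relative risks `RR(Cn) = 1 + α(1 − exp(−γ(Cn − Cn_cf)^δ))` above the
counterfactual `Cn_cf = 5.8 µg m⁻³`, and attributable deaths
`ΔM = BM·(RR−1)/RR·Pop` with a 95% CI from the baseline-mortality CI.

A first-class synthetic-data module generates every input (gappy satellite
AOD, reanalysis AOD, meteorology, land cover, roads, monitors, population
and baseline-mortality tables) from a known ground truth, so each stage has
exact-recovery and statistical-recovery tests without any downloads. See
`docs/methods.md` for the model details, generator design and limitations.

## Worked example

```python
from aodpm25 import integrate, stage1, stage2, validate
from aodpm25.grid import GridSpec
from aodpm25.synthetic import TruthConfig, default_dates, simulate_fixture

grid = GridSpec(lat0=21.3, lon0=74.4, n_lat=40, n_lon=50)          # 0.03° cells
bundle = simulate_fixture(grid, default_dates(2018, 150),
                          TruthConfig(seed=7, n_stations=30))

# stage 1: fill satellite gaps from the reanalysis link
coeffs = stage1.fit_gridwise_regression(bundle.aod.satellite, bundle.aod.reanalysis)
final_aod, provenance = stage1.impute_aod(bundle.aod.satellite, bundle.aod.reanalysis, coeffs)
diag = stage1.imputation_diagnostics(coeffs)
print(f"imputation: coverage={diag['coverage']:.3f}  mean r2={diag['mean_r2']:.3f}")

# collocate everything into the analysis table and screen extremes
static = {"urban": bundle.static.urban, "grass": bundle.static.grass}
table = integrate.collocate(bundle.monitors, final_aod, provenance, bundle.met, static)
table, removed = integrate.screen_extremes(table)     # drops > 99.9th percentile

# stage 2: day-random-effects model
fit = stage2.fit_lme(table.dropna(subset=["aod"]))
print(fit.summary_table())

# stages 2+3 under tenfold cross-validation
cv_table, metrics = validate.cross_validate(table, k_folds=10, seed=0)
for name, m in metrics.items():
    print(f"{name}: CV r2={m.r2:.3f}  RMSE={m.rmse:.2f}  MAE={m.mae:.2f}")
```

prints (exact numbers for this seed):

```
imputation: coverage=0.980  mean r2=0.630
 Variable  Coefficient  Std.Err  p-value
intercept    -1159.873   38.707    0.000
      aod       40.816    2.500    0.000
     temp       -1.781    0.146    0.000
       rh       -3.159    4.334    0.466
      v10       -1.106    0.301    0.000
     pres        0.012    0.000    0.000
    urban        0.541    0.046    0.000
    grass        3.130    0.054    0.000
stage2: CV r2=0.698  RMSE=18.52  MAE=14.61
stage3: CV r2=0.810  RMSE=14.97  MAE=11.56
```

Reading this: 98% of cells had enough paired days to fit their own AOD
link, and the link explains ~63% of the satellite AOD's temporal variance.
The mixed model finds PM2.5 rising with AOD, pressure and urban/grassland
cover and falling with temperature — and the GWR stage, which models the
*spatially varying* part of the AOD–PM2.5 relationship, lifts held-out CV
r² from 0.70 to 0.81 and cuts RMSE from 18.5 to 15.0 µg m⁻³ on this
30-monitor fixture. (RH is attenuated toward zero here: its within-day
signal is small against the fixture's residual noise.)

## Command line

The same pipeline runs end to end from a YAML config:

```bash
aodpm25 --verbose run-all --config run.yaml     # or: simulate | impute |
                                                # integrate | fit-lme |
                                                # fit-gwr | cv | burden
```

Every run writes its intermediates (fixture NetCDF/CSV, `final_aod.nc` with
provenance, LME summary, per-day GWR summaries, daily/annual/seasonal PM2.5
surfaces, CV report, mortality table) plus a manifest recording the seed,
config hash and per-stage status. A fixed seed reproduces every artifact
byte for byte.

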