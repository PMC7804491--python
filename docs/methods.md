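# Methods

This note documents the statistical model the package implements, the
synthetic study domain it is tested on, the numerical choices made where the
design was genuinely open, and the known limitations.

## The three-stage model

The pipeline converts a gappy satellite aerosol optical depth (AOD) product,
a complete reanalysis AOD product, gridded meteorology and static land-use
layers into spatially continuous daily surface PM2.5 on a 0.03° rectilinear
grid, then into district-level premature-mortality estimates.

**Stage 1 — AOD gap imputation.** For each grid cell *s* and year, ordinary
least squares of satellite AOD on reanalysis AOD over the days where both
exist gives (α_s, β_s); a missing satellite value on day *t* is replaced by
α_s + β_s·AOD_rean(s,t), clipped below at zero. Cells with fewer than
`n_min = 10` paired days (or a degenerate regressor) borrow the mean
coefficients of their 8-neighborhood, falling back to a domain-pooled
regression; both are flagged in a per-value provenance mask
(observed / imputed / fallback / missing). Observed values are never
altered. Per-cell r², slope, intercept, slope p-value (two-sided t) and the
fraction of cells with p > 0.01 are reported.

**Stage 2 — linear mixed-effects model.** Station-day PM2.5 is regressed on
imputed AOD, 2 m temperature (°C), relative humidity (fraction 0–1), one
10 m wind component (northward by default; eastward is configurable),
surface pressure (Pa), and urban / grassland fine-cell counts. The
intercept and the five meteorology/AOD slopes carry day-level Gaussian
random effects with a diagonal covariance Σ — the package deliberately
implements only the diagonal structure: with ~12 observations per day a
full 6×6 Σ is far beyond what the data identify, and the diagonal model is
the generative model of the synthetic domain. Estimation maximizes the
restricted likelihood
profiled over the fixed effects and the residual variance: with variance
ratios θ = diag(Σ)/σ², each day's marginal covariance is
σ²(I + Z_t Θ Z_t′), and the Woodbury identity reduces every evaluation to
batched q×q solves over per-day cross-product matrices. L-BFGS-B on log θ
runs from three starts (the profiled criterion has a spurious
"all variance on the intercept" local optimum when random-slope covariates
have large means relative to their within-day spread) and polishes the best
at `ftol = 1e-8`; non-convergence is an explicit status. The test suite
cross-checks the estimator against an independent mixed-model
implementation (statsmodels `MixedLM` under the same diagonal constraint).

*Standardization.* The fixed design is centered and scaled internally
(surface pressure is ~1e5 Pa against AOD ~0.4); the random design is only
scaled. Centering a covariate that carries a random slope would fold that
slope's variance into the day intercept, and a diagonal Σ would then no
longer describe the stated model. All reported quantities are
back-transformed to original units exactly.

*Covariate selection.* Candidate covariates (road density, boundary-layer
height, cropland) enter as fixed effects; any candidate with p > 0.05 is
dropped and the model refitted, with a decision log.

**Stage 3 — daily geographically weighted regression.** Stage-2 residuals
(observed − predicted at station-days) are regressed on AOD locally: at
each calibration point, weighted least squares with the adaptive bi-square
kernel w = (1 − (d/h)²)² for d < h. The bandwidth h at a kernel center is
the great-circle distance to its k-th nearest calibration point — excluding
zero-distance points, so the local fit always sees k neighbors plus the
center — inflated by (1 + 1e-6) so the k-th neighbor has positive weight.
k is selected per day by minimizing

AICc = 2n·ln(σ̂) + n·ln(2π) + n·(n + tr S)/(n − 2 − tr S),  σ̂² = RSS/n,

with tr S the hat-matrix trace, by exhaustive search over k for n ≤ 50
calibration points and integer golden-section beyond (the two coincide
whenever the AICc curve is unimodal in k; noisy small-n curves can have
flat multimodal tails, which is why exhaustive search is the small-n
default). Ties go to the smaller k. Days with fewer than `k_min = 6`
points, or with no k giving n − 2 − tr S > 0, fall back to a pooled
("global") OLS of residual on AOD. Prediction at unsampled cells re-centers
the kernel at the cell (same k) and applies the locally refitted
coefficients to the cell's imputed AOD. The final surface is the stage-2
prediction plus the stage-3 residual surface, floored at 0.5 µg m⁻³;
annual and IMD-season means (winter JF, pre-monsoon MAM, monsoon JJAS,
post-monsoon OND) are derived from the daily maps.

**Validation.** Tenfold cross-validation partitions station-day rows at
random into near-equal folds (sizes differ by at most one); stages 2 and 3
are refitted per fold, including per-day bandwidth reselection, and metrics
(r² as squared Pearson correlation, RMSE, MAE, OLS and forced-origin
slopes) are computed on the pooled held-out predictions. Station-wise
summaries and a separate metric set restricted to rows whose AOD was
imputed (the skill bought by gap filling) are reported. The AOD imputation
stage uses no PM2.5 and is fitted once outside the CV loop — no leakage is
possible through it.

**Health module.** District population-weighted exposure
Cn = Σ pop·pm25 / Σ pop feeds the integrated exposure–response function
RR(Cn) = 1 + α(1 − exp(−γ(Cn − Cn_cf)^δ)) for Cn > Cn_cf = 5.8 µg m⁻³ and
RR = 1 otherwise; a lookup-table mode linearly interpolates tabulated
(Cn, RR) pairs, clamped at the ends. Attributable deaths use the standard
attributable fraction: ΔM = BM·((RR − 1)/RR)·Pop, evaluated at each
baseline-mortality CI bound — only BM uncertainty is propagated, by design.
The shipped disease/age IER parameters are illustrative placeholders with
the right qualitative shape (risk ceilings falling with age for ischemic
heart disease and stroke); they are not GBD estimates and are flagged as
such. A printed literal reading of the attribution formula ("RR − 1/RR")
would give nonzero deaths at RR = 1, contradicting the null contract below
the counterfactual; the attributable-fraction form is used.

## The synthetic study domain

The generator produces every pipeline input from a known ground truth on a
default 40×50-cell, 0.03° domain over 365 days with 12 monitors — a desk
scale of the emulated study region. All spatial structure is built from
low-order random harmonic surfaces (cheap, smooth, reproducible); all
randomness derives from a single seed through named substreams, so a fixed
seed yields a byte-identical fixture bundle.

- **AOD pair.** Reanalysis AOD is lognormal with a smooth spatial base,
  daily level shifts and a low-rank spatio-temporal term — always positive
  and gap-free. Satellite AOD is α_s + β_s·rean + noise (α ≈ 0.05,
  β ≈ 1.15 with smooth spatial variation), negative draws clipped at zero
  and counted. The link noise sd of 0.11 puts the per-cell temporal r²
  near 0.6, the level real satellite/reanalysis pairs exhibit over this
  kind of region. Missingness is seasonal (winter 0.25, pre-monsoon 0.30,
  monsoon 0.65, post-monsoon 0.35) plus one contiguous "water" blob (~2% of
  cells) that never reports.
- **Meteorology.** Each variable is mean + seasonal cosine + smooth spatial
  surface, clipped to physical ranges (RH to [0,1]); setting the amplitudes
  to zero gives constant fields, which the degenerate-configuration tests
  use.
- **PM2.5 truth.** The stage-2 linear model with the reference fixed
  effects (intercept −823.031; AOD 34.833; temperature −1.104; RH −23.502;
  northward wind −1.178; pressure 0.009; urban 0.100; grassland 0.796), day
  random effects with sds (5, 10, 0.5, 8, 0.5, 2e-5), a spatially varying
  residual AOD slope b1(s), and a residual split into a spatially smooth
  day-specific field (sd 7 µg m⁻³) plus i.i.d. noise (sd 7 µg m⁻³). Values
  are floored at 0.5 µg m⁻³ with the flooring rate reported.
  The smooth day-error component reflects regional misfit events (synoptic
  transport, plumes) that day-level random effects cannot absorb; with
  purely i.i.d. errors the synthetic residuals would contain none of the
  within-day spatial structure the GWR stage exists to capture.
- **Residual slope field.** b1(s) varies at regional scale (two harmonic
  modes, under one cycle across the domain) with amplitude 28, i.e. a
  residual spatial signal of roughly 13 µg m⁻³ sd at mean AOD ≈ 0.5 —
  the magnitude implied by the reported stage-2→stage-3 CV RMSE improvement
  at a ~12-station network.
- **Monitors.** Placed at distinct cells with probability proportional to
  population (regulatory networks are urban), observing truth plus Gaussian
  noise (sd 5 µg m⁻³); with probability 0.001 an observation is replaced by
  an extreme value in [500, 1000] µg m⁻³ to exercise the 99.9th-percentile
  screen.
- **Static layers.** Urban hotspots with distance-decaying urban
  probability; patchy grass/crop propensities (smooth regional surface plus
  fine-scale noise, so every cell's counts vary); roads connecting hotspots
  plus random segments; rectangular districts (4×5 blocks); population from
  a lognormal background plus urban mass; district × age × disease
  baseline-mortality tables with ordered CIs and age shares partitioning
  the 25+ population.

What the generator does **not** emulate: satellite swath geometry and cloud
physics, curvilinear tile projections, temporal autocorrelation in monitor
noise, station-specific persistent site biases, and real GBD
baseline-mortality or IER values. Passing tests therefore demonstrate
correctness of the estimators under the stated generative assumptions, not
real-data skill.

## Numerical choices

- Great-circle distances by haversine on a sphere of radius 6371.0088 km.
- Cell membership is half-open (center ± cell/2, lower edge inclusive); no
  point is counted twice.
- Screening threshold: type-7 (linear-interpolation) quantile over the whole
  table at once; a frozen threshold can be passed to make re-screening a
  no-op.
- Local GWR fits with weighted AOD variance < 1e-10 fall back to the
  weighted-mean-only model and are logged.
- REML convergence: relative criterion change ≤ 1e-8, ≤ 200 iterations,
  finite-difference step 1e-5 in log-variance-ratio space (the default 1e-8
  sits below the criterion's cancellation noise floor when R² ≈ 1).
- Fold assignment: seeded permutation, fold sizes differing by at most one.
- NetCDF output uses CF-style time/lat/lon coordinates with a declared
  `_FillValue` (scipy backend, NetCDF3).

## Test problem sizes

Module tests run on a 20×24-cell, 120-day, 12-monitor bundle. Recovery
checks use the full 40×50 domain: stage-1 unbiasedness over ≥ 500 cells and
365 days; stage-2 recovery over 20 replicates of 365 days × 12 stations
(with the generating AOD as covariate, isolating the estimator from
stage-1 error-in-variable attenuation, which is ~13% on the AOD slope at
default gap and noise levels). The stage-3 directional-improvement check
runs 20 replicates of 150 days with a 30-monitor network: at 12 stations,
per-fold-refit daily GWR adds more estimator variance than it removes bias
under every realistic noise level we tested, so the regional residual
field must be sampled densely enough to be resolvable — see Limitations.

## Limitations

- With ~12 monitors, the daily GWR stage is near-degenerate: AICc selects
  near-maximal smoothing, local slopes are weakly identified, and honest
  (per-fold-refit) cross-validation shows no improvement over the LME
  stage. The directional benefit of GWR emerges at denser networks or
  stronger/smoother residual structure. Published improvements at sparse
  networks may additionally reflect residual spatial structure absent from
  this generator (e.g. persistent site biases) or CV schemes that do not
  refit the GWR per fold.
- Σ is diagonal by default; the unstructured option is not exercised by the
  acceptance suite.
- Variance components on near-constant standardized regressors (e.g. the
  pressure slope) are weakly identified at 12 observations per day; fixed
  effects and their SEs are unaffected, but Σ estimates can trade off
  against the day-intercept variance.
- The IER parameters shipped are illustrative; substantive burden numbers
  require externally supplied parameter or lookup tables.
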