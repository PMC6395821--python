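# Methods

This note documents the models, the synthetic world, the numerical
choices, and the known limits of `thermoselect`.

## Estimation target

The package estimates an exponential resource selection function (RSF)
w(x) = exp(β·z) from a used/available design: each observed animal
location (used, coded 1) is paired under a stratum ID with k uniform
random points (available, coded 0) drawn from an availability domain, and
β is estimated by maximum-likelihood logistic regression on the pooled
rows. For an exponential RSF this logistic fit consistently estimates the
log density ratio of used to available covariates; the intercept absorbs
the used:available ratio and is dropped at scoring time. Covariates are
standardized (z = (x − mean)/SD) with table-wide statistics computed once
on the fitting table and frozen in `ScalingParams`, because projections
must standardize shifted covariates with the *original* statistics —
re-standardizing at projection time would silently absorb the climate
signal.

Two availability scales are supported: the population-level home range
(100% minimum convex polygon of all used points) and per-observation
circles whose radius follows monthly mobility. Available rows inherit the
contextual attributes of their used row (individual, timestamp, group
size, wind), so context covariates are constant within a stratum.

### Random effects

The field protocol suggests random intercepts for stratum-within-
individual and for group. The default estimator is nevertheless the
fixed-effects logistic fit: in this design the stratum intercepts carry no
information about selection, and in practice their estimated variances
collapse to zero. Mixed estimation is available behind
`fit(method="mixed")`: a Laplace approximation whose objective — the
integrated likelihood approximated at the conditional mode of the random
intercepts — is maximized jointly over the fixed effects and the
log-standard-deviations, the same criterion `lme4::glmer` uses at its
default accuracy. The implementation uses dense linear algebra and is
intended for small-to-moderate problems; a test cross-checks it against
`glmer` through `Rscript` on a grouped fixture with genuine between-group
variance (agreement to ~1e-3). Variances estimated below 1e-6 are reported
as exactly 0 and the fixed-effects fit is returned, so marginal and
conditional R² coincide in that case.

### Inference conventions

Standard errors are observed-information Wald SEs; p-values are two-sided
normal on z = β̂/SE. AIC is 2k − 2·logLik with k counting fixed
coefficients plus estimated variance components. The latent-scale
binomial R² partition is marginal = var(Xβ)/(var(Xβ) + Σσ² + π²/3),
conditional = (var(Xβ) + Σσ²)/(same denominator).

## Thermal field

Logger temperature is modelled as

    T_logger(t) = a + b·T_station(t) + lapse·(elev − elev_station)
                  + offset[sector] + ε,

fitted by ordinary least squares with the first sector as reference. The
linear form honours a deployment stratified by elevation and
hydro-geographic sector; hour-of-day interactions are deliberately not
included (whether the original interpolation had them is unknowable from
the available description; the linear core is the tested surface, and the
design-matrix construction is extensible). Maximum daily temperature is
computed by evaluating the fitted model at every station hour of the date
and taking the per-pixel maximum — 24 evaluations rather than a second
fitted model, which keeps max-daily exactly consistent with (and bounded
below by none of) the hourly predictions.

## Synthetic world

The generator exists to give every stage a ground truth. It emulates:

- a ~1700-ha glacial valley (10 m grid, 1700–3300 m) with a west floor and
  north-east ridges: trend + Gaussian-smoothed relief, rescaled exactly to
  the configured elevation range; slope/aspect by centred finite
  differences (aspect is the compass direction of steepest descent;
  cos-aspect is +1 north-facing), Riley ruggedness from the 8-neighbour
  differences;
- NDVI declining linearly with elevation plus smooth noise, generated at a
  25-cell (250 m) block grid and resampled to 10 m — reproducing the
  satellite/DEM scale mismatch of real inputs;
- hiking trails along the valley floor (log-distance raster), a 4-class
  land cover, and "safe areas" = scree/rock steeper than 45° (30°
  selectable), with Euclidean distance rasters;
- hourly station weather: seasonal half-sine + diurnal cosine peaking at a
  configurable hour + Gaussian noise; wind speed, cosine wind direction
  (+1 north, −1 south) and daytime solar radiation;
- a logger network (default 17, stratified over elevation × sector) whose
  series follow the station by the same linear lapse/sector structure the
  thermal model fits — so the generator is the oracle for recovery tests;
- grouped observations: sighted individuals are partitioned into social
  parties (sizes 1 + Poisson, mean ≈ 2.9), each party draws one pixel with
  probability ∝ exp(β·z) under the window's context (date, hour, wind),
  members scatter within the 50-m grouping distance, and co-located
  parties are merged by the field rule (group size = member count, one
  shared centroid location). Survey windows are hard dawn/dusk windows
  (05–09 h, 16–20 h). Defaults mirror a two-season effort (57 individuals,
  163 days, ≈3,300 sightings in ≈1,100–1,300 groups).

A faster stratified generator (`simulate_used_available`) skips the
spatial bookkeeping: it draws used pixels ∝ exp(β·z) and available pixels
uniformly from a pixel pool. Because both the generator and the fit use
the pooled standardization, recovery is exact in expectation and the
logistic model is correctly specified, which is what makes the 95% CI
calibration check meaningful.

The two-metric generator (`simulate_two_metric_strata`) makes the
max-daily vs hourly hypotheses separable under pooled fitting. A
spatially uniform diurnal cycle would render the two metrics identical
within a stratum (they would differ by a per-stratum constant that the
within-stratum selection cannot see). The generator therefore models the
morning-inversion pattern of alpine valleys: the hourly field is the
max-daily field minus a small uniform deficit, plus an hour-dependent
lapse modulation around the mean elevation (surface lapse near zero
before dawn, steepest at the afternoon peak). Each metric is then
identifiable when it is the true driver, in both directions.

What the generator does **not** emulate: real topography or satellite
compositing, GPS-collar movement, predator dynamics, spatial
autocorrelation of residual selection, observer detection bias, or
phenological NDVI change. Passing tests therefore demonstrate the
correctness of the machinery under the stated data-generating
assumptions, not the field conclusions themselves.

## Screening protocol

Covariates are reduced until all pairwise |Pearson r| ≤ 0.7 and all
VIF ≤ 3 (the field's customary thresholds). When a pair violates the
threshold, the dropped member is decided *conditionally*: both members
enter one joint logistic fit on the used/available label, and the one
with the smaller Wald |z| drops — for a covariate and its noisy shadow
the informative member keeps its |z| while the shadow's collapses, which
makes the decision far more stable than any marginal importance contrast
between near-duplicates. A configured domain override takes precedence
(e.g. keep NDVI over elevation for its ecological relevance), and a
singular joint fit falls back to the importance ranking. The reported
importance ranking — also used to choose which covariate leaves in the
VIF loop — is the out-of-bag AUC of a random forest (default 500 trees)
grown on each covariate alone; scoring covariates one at a time avoids
the substitution effect that flattens joint-forest permutation
importances across collinear features. Ties break alphabetically (the
later name drops). Constant covariates are dropped first with reason
"zero variance". Re-running the screen on its retained set is a no-op
(tested).

Step-AIC is deterministic greedy backward elimination: at each step, among
terms not nested in any retained higher-order term (marginality), drop the
one whose removal lowers AIC most; stop when none does. The original
"manual" removal order is not recoverable, so determinism is preferred.
Note the statistical ceiling of this procedure: a single pure-noise
parameter is removed exactly when its likelihood-ratio statistic is below
2, which happens with asymptotic probability P(χ²₁ < 2) ≈ 0.843 regardless
of sample size. Candidate fits that fail to converge are skipped and
logged.

## Validation

Boyce-style area-adjusted k-fold validation (default k = 5, 10 bins).
Folds partition *strata* (individual-level partitioning is available), so
a used point and its availables never straddle folds. Per fold: fit on the
other folds, score the withheld fold, bin scores by the deciles of the
training folds' available-point scores (equal-availability bins; fixed-
width binning selectable — the binning rule is a package choice), compute
the area-adjusted frequency of withheld used points (used/available count
ratio per bin, normalized to sum 1), and take the Spearman correlation
(average ranks on ties) between AAF and bin rank. Bins with no available
points are flagged, logged, excluded from the correlation, and the
remaining AAF renormalized. Outer bin edges extend to ±∞ so withheld
scores outside the training range still bin.

## Projection

For each climate-ensemble member, ΔT = member's scenario-year August mean
maximum-daily temperature minus the observed-baseline August value at the
same reference definition (the station value by default — which observed
surface anchored the original baseline is not stated, so it is
configurable). ΔT is applied as a uniform additive shift to the
interpolated max-daily field; no downscaling. All other covariates are
frozen at baseline (explicitly a best-case assumption). Scenario context
defaults: Julian day 233 (the hottest-day convention), group size 2 and
median August wind. Each member is projected individually and the member
maps are then averaged (mean and sample SD per pixel): for an exponential
model the mean of projections differs from the projection of the mean ΔT,
and the member-wise order of operations is the documented one (tested).

"Range retention" needs a definition of *selected area*, which the source
material leaves open. The default rule is `score_above_1` — selection
above the all-covariates-at-fitting-mean baseline, the natural reference
for an intercept-free exponential RSF — with `quantile(q)` (threshold at
the baseline's q-quantile) and `difference_positive` (fraction of the
range scoring higher in the future) selectable. Retention is
area(selected, future)/area(selected, baseline). Elevation profiles
min-max standardize scores to [0, 1], average them in elevation bins, and
smooth with a cubic smoothing spline; the selection-weighted mean
elevation Σ(w·elev)/Σw uses raw scores as weights.

## Used/available table: column dictionary

The CSV written by the design stage has one row per point:

| column | meaning |
| --- | --- |
| `stratum_id` | pairing code: one used location + its k availables |
| `case` | 1 = used, 0 = available |
| `x`, `y` | world coordinates (m) |
| `individual_id`, `group_id`, `group_size` | inherited from the used observation |
| `timestamp`, `julian_day` | observation time, shared within the stratum |
| `elevation`, `slope`, `cos_aspect`, `ruggedness`, `ndvi`, `log_dist_trail`, `dist_safe`, `landcover`, `sector` | pixel covariates at the point |
| `t_hourly`, `t_max_daily` | thermal-model predictions at the point's pixel for its hour / date |
| `wind_speed`, `cos_wind_dir`, `solar` | station values at the observation hour |
| `z_<name>` | the standardized version of each numeric covariate |

## Numerical choices and degenerate inputs

- Logistic fits: Newton with tolerance 1e-10 (500 iterations), falling
  back to L-BFGS; non-convergence raises with the term list (separation
  diagnosis), constant columns raise naming the column.
- Laplace mixed fits: Nelder-Mead over (log σ, β), xatol 1e-5, fatol 1e-8;
  inner Newton on the random-intercept mode to 1e-12 with step halving.
- Grids smaller than 3×3 are rejected (finite differences undefined); flat
  cells get cos-aspect 0; a flat DEM yields an empty safe mask and a
  degenerate (warned) elevation profile.
- Collinear location sets reject MCP construction; zero-variance
  covariates reject standardization by name; rank-deficient thermal
  designs (single-elevation logger networks) raise naming the elevation
  term.
- Availability sampling is rejection sampling against the domain and the
  nodata mask; a fully-nodata domain raises after a bounded number of
  rounds. Points on nodata pixels are dropped with a logged count at
  covariate attachment.
- Sensitivity stabilization: the reported ratio is the smallest from which
  all successive maximum relative coefficient changes stay below 5%;
  coefficients below 0.1 in magnitude (a negligible standardized effect)
  count as unchanged — without such a floor, relative change is undefined
  at the null.
- Random streams: every stochastic operation takes an explicit integer
  seed; the pipeline derives stage seeds by fixed offsets from the global
  seed, and the run manifest records SHA-256 hashes of every artifact so
  bit-level reproducibility is checkable.

## Problem sizes

The test suite and the acceptance script run the replicate studies at
2,000 strata (1:15) for recovery, 1,000 strata for model-selection and
pruning replicates, 60×60–80×80 pixel worlds for spatial stages, and a
40×40 world for the end-to-end smoke chain. These sizes were chosen so
each property is measured with comfortable statistical margin while a full
run stays in the minutes range on a single CPU; all of them scale up by
configuration only.

## Known limitations

- The thermal model is air temperature only: no operative-temperature
  (radiation/wind/conduction) modelling.
- The Laplace mixed estimator is dense and not intended for tables with
  tens of thousands of strata as intercept levels.
- The continuous (moving-window) Boyce index is not implemented; only the
  binned variant.
- Projection treats ΔT as spatially uniform and leaves NDVI, wind and
  phenology unchanged — a stated best-case scenario, not a forecast of
  the covariates themselves.
- Rasters are exchanged as ESRI ASCII grids; CRS metadata beyond the
  affine grid is not carried.
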