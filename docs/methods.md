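# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `cyclexpo`.

## Observation model

The analysis unit is the one-minute trip segment. For each of the three
responses — noise exposure L_Aeq,1min (dB(A)), NO₂ concentration (µg/m³) and
inhaled NO₂ dose (µg/min) — the model is a generalized additive mixed model
with a moving-average residual term (GAMMAR):

    y_t = β₀ + x_tᵀβ + f(clock_t) + g(u_t, v_t) + b_day(t) + b_part(t) + r_t
    r_t = e_t + θ₁ e_{t−1} + θ₂ e_{t−2} + θ₃ e_{t−3},  e_t ~ t_ν(0, σ)

- **Fixed effects** x: the fractions of the minute spent on each of five
  road classes (trunk/motorway, primary, secondary, tertiary,
  unclassified/service) relative to the residential-street reference, mean
  speed (km/h), mean grade (%), the number of degree-≥3 network nodes
  crossed, and — in the NO₂ and inhalation models only — relative humidity
  (%) and wind speed (km/h). The noise model excludes the weather terms.
- **Smooths**: f is a cubic B-spline in minutes-since-08:00 (default 8
  basis functions, first column dropped after centring); g is a
  thin-plate-type radial basis (φ(r) = r² log r on the scaled plane, knots
  on a regular grid over the observed bounding box, default ~30 functions,
  plus centred linear terms). Both bases are column-centred over the
  training observations, so the smooths average to zero over the observed
  support and the intercept carries the overall level.
- **Random intercepts**: crossed day and participant effects (5 days, 3
  riders by default).
- **Residuals**: MA(3) with heavy-tailed Student-t innovations (ν = 4 by
  default, configurable; ν must exceed 2 so the variance exists). The MA
  process resets at trip boundaries — consecutive minutes are correlated
  only within a trip.

The inhaled dose is defined per minute as I = (VE × 0.001) × NO₂, with VE
the minute ventilation in L/min; noise aggregation uses the 3 dB exchange
rate throughout, i.e. levels combine as 10·log10 of mean energy.

## Estimation

Estimation is an iterated two-stage feasible GLS:

1. **Variance components** for the crossed random intercepts are estimated
   once by REML (a linear mixed model with two variance components and a
   single group, fit with statsmodels MixedLM), ignoring the MA term. If
   REML does not converge under any of three optimizers, deterministic
   ANOVA-type moment estimates are used instead (recorded in the fit's
   variance-component metadata). These components are then held fixed; they
   control only the BLUP shrinkage and contribute little to fixed-effect
   uncertainty at this design size.
2. **Smoothing**: the spline blocks carry a ridge penalty whose weight is
   chosen by generalized cross-validation on the first-stage (OLS) fit over
   the grid {0, 0.01, 0.1, 1, 10, 100}, then held fixed.
3. **Iteration** (to a 1e-4 relative-change tolerance, max 20 passes):
   - whiten each trip block with the Cholesky factor of the MA(3)
     covariance implied by the current θ;
   - for the Student likelihood, apply IRLS weights
     w_t = (ν+1)/(ν + e_t²/σ²) to the whitened rows;
   - solve the penalized GLS normal equations with the random-effect
     covariance folded in by the Woodbury identity (the per-trip blocks keep
     this O(n) in the number of segments); BLUPs come from the same solve;
   - re-estimate θ by conditional least squares on the per-trip ordered
     conditional residuals (innovations reconstructed with `lfilter`,
     pre-sample values zero, box constraints |θⱼ| ≤ 0.98), and σ² from the
     weighted innovations.

A fit that exhausts the iteration budget reports `converged = False` and
refuses to predict.

**Uncertainty.** Intervals are Wald and labelled as such. The fixed-effect
covariance is a delete-one-trip jackknife around the final whitened GLS
solve, multiplied by the Student-ML factor (ν+3)/(ν+1) — the IRLS solve
conditions on the robustness weights, which hides exactly that share of the
heavy-tailed likelihood's variance — with t(m−1) critical values for m
trips. The MA coefficients use a delete-one-trip jackknife of the CLS step.
This combination was chosen over (a) the plain model-based GLS covariance
and (b) a CR0 cluster sandwich, both of which undercover in simulation with
~15 trips and t₄ innovations; the jackknife also stays honest when residual
dependence is imperfectly captured by the MA(3) term (e.g. wind is constant
within half-hour blocks). Simulation calibration: over 20 replicates of the
default scenario, 95% intervals for the primary-road effects and the MA
coefficients cover the generating values in ≥ 90% of replicates (the
acceptance suite re-runs this check).

**Explained variance** is reported as a variance partition: the marginal R²
is var(fixed + smooth fitted values) over that plus random-effect and
residual variance; the conditional R² adds the random-effect contribution to
the numerator. Marginal ≤ conditional by construction.

**Degenerate limits.** With no smooths, no random effects, no MA term and a
Gaussian likelihood the estimator reduces exactly to OLS (verified to 1e-6
in the tests); with `ma_order=0` on MA data the residual ACF reproduces the
generating MA autocorrelation, which the diagnostics expose.

## The synthetic-data generator

The generator emulates a five-day, three-rider mobile-sensing campaign in a
large polluted city and is the package's sole data source.

- **Road network**: nodes uniform on a 5 km × 5 km plane (planar metres —
  no geographic CRS, so distances and buffers are exact), edges from the
  Delaunay triangulation (connected and planar by construction), each edge
  assigned one of six road classes (uniform mix by default) and a small
  normal grade (SD 1.2%, clipped at ±6%).
- **Trips**: random walks over the network at 1 Hz; per-minute speed is
  lognormal around 17 km/h (CV 0.1). Default scale is 15 trips × 200 min =
  3,000 segments, rostered round-robin over 3 participants × 5 days, with
  start times rotating through day slots so the 08:00–18:00 window is
  covered evenly.
- **Mean structure**: the default scenario's intercepts, fixed effects,
  day/participant intercepts and MA coefficients are the point estimates of
  a published field study of cyclists' exposure in a heavily polluted
  megacity, used here as generating truth for parameter-recovery testing.
  The spatial fields are sums of two opposite-signed Gaussian bumps with
  peak-to-trough extents 4.5 dB(A) and 70 µg/m³ (the inhalation field is
  the NO₂ field scaled by the mean ventilation, ~2.5 µg); the NO₂
  time-of-day profile is a Gaussian pulse peaking at 13:00 with a ~100
  µg/m³ swing; the noise time profile is flat. Fields and profiles are
  centred to mean zero over the domain/day so the intercept is identified.
- **Ventilation**: VE = 20 + 0.8·speed + 1.5·max(grade, 0) L/min, truncated
  to [10, 80], plus MA(3) Student-t noise — about 34 L/min at 17 km/h,
  consistent with an urban cyclist. The inhaled-dose response is generated
  exactly as (VE × 0.001) × NO₂ per minute, so its mean structure satisfies
  the inhaled-dose identity and its extra dispersion enters through the VE
  and NO₂ noise rather than an additive error of its own.
- **Weather**: humidity is a per-day offset plus a slowly-drifting AR(1)
  around 46% (marginal SD ≈ 8%); wind is piecewise constant per half-hour
  with a 36% point mass at zero and mean ≈ 9 km/h otherwise.
- **Residual scales** (innovation σ: 2.3 dB(A), 35 µg/m³, and 7 L/min for
  VE) were set so the marginal response dispersions approximate the field
  study's descriptive SDs (≈ 4 dB(A), ≈ 79 µg/m³, ≈ 4.3 µg); the simulated
  marginal means land within ±10% of the published descriptive means, which
  the calibration test checks.

What the generator does **not** emulate: sensor cross-sensitivity (e.g. NO₂
sensors responding to O₃), battery gaps, GPS positional error,
map-matching error (simulated fixes are on-network by construction),
particulate matter, and real street-network topology (types are assigned
independently of location, so road class and the spatial field are
unconfounded by design — real cities are less kind). Passing tests
therefore demonstrate correctness of the machinery and calibration of the
estimator under the stated generating process, not field validity on any
real city's data.

## Segmentation rules

- GPS fixes join the sensor record of their containing minute; fixes
  outside sensor coverage are dropped and counted.
- One segment per complete sensor minute; a trailing/leading partial minute
  with ≥ 30 s of fixes is kept and flagged `partial`, shorter ones are
  discarded (the field protocol is silent here; this keeps trip ends
  without letting unstable covariates in).
- Road-class shares are time shares from 1 Hz fix counts (not distance
  shares), matching a "time spent per road type" covariate definition.
- Intersections are distinct degree-≥3 network nodes traversed within the
  minute, detected at edge transitions.
- The decibel SD in descriptive tables is defined on the energy scale as
  10·log10(1 + sd_E/mean_E) — zero for a constant series and consistent
  with the energy mean; conventions differ across the field, so this one is
  stated explicitly.
- A ppm ↔ µg/m³ conversion (1 ppm NO₂ = 1880 µg/m³ at 25 °C, 1013 hPa) is
  provided for sensors specified in ppm; synthetic data is generated in
  µg/m³ directly.

## Descriptive statistics

Percentiles interpolate linearly between order statistics. The ACF index is
the lag-k Pearson correlation computed within trips and pooled with
(length − k) weights — it never crosses trip boundaries. Moran's I uses
binary distance-band weights (w_ij = 1 iff 0 < d_ij ≤ d) on segment
midpoints; a scan over d ∈ {50, …, 500} m (step 50) reports the maximum and
its band. Midpoint distance is used rather than true line-segment distance
for simplicity; with ~280 m between consecutive-minute midpoints the two
differ little at these band widths.

## Dose and hazard

Noise dose D = (100/T_c) Σᵢ Tᵢ·10^((Lᵢ−L_c)/q) with defaults L_c = 59.3
dB(A), T_c = 24 h, q = 10 (3 dB exchange rate). The criterion level is
configurable (health-guideline documents also cite 59.9 dB in places).
Minutes-to-dose inverts this in closed form and is an exact inverse
(verified to 1e-9). Intake thresholds multiply the 1-hour NO₂ guideline
(200 µg/m³) by ventilation and duration: 180 µg at 15 L/min (pedestrian),
420 µg at 35 L/min (cyclist).

Hazard curves hold covariates at supplied means, the clock at 11:00, exclude
random effects, and predict a constant per-minute level per (location, road
type); doses accumulate linearly and crossings are interpolated to 0.1 min.
"Low/moderate/high" locations are the 25th/50th/75th percentile points of
the generating NO₂ spatial field within the observed route bounding box
(predictions outside the fitted spatial support would extrapolate and are
flagged). Published per-city crossing minutes depend on that city's fitted
smooths and are not reproduction targets; the machinery is validated through
the closed-form identities instead.

## Pipeline and reproducibility

`run_pipeline` executes simulate → segment → describe → fit → hazard from a
fully-defaulted YAML-serialisable config; every run directory gets a
manifest with the seed, a config hash, per-stage timings and artifact
checksums. All randomness flows from integer seeds through
`numpy.random.default_rng`; reruns are bit-identical. The end-to-end run at
fixture scale (3 trips × 60 min) completes in seconds; the default study
(3,000 segments, three model fits) takes under half a minute on one CPU.

## Known limitations

- The Bayesian analogue (MCMC posterior inference) is not implemented; the
  two-stage backend with Wald/jackknife intervals is the only estimator,
  and its intervals are frequentist, not posterior, quantities.
- Variance components from 5 days and 3 participants are inevitably noisy;
  they are treated as nuisance shrinkage parameters, and the intercept's
  interval is accordingly wide.
- Smoothing-parameter uncertainty is ignored after GCV selection.
- Interval calibration for covariates that are block-constant in time
  (wind) or nearly confounded with the time smooth (humidity) sits slightly
  below nominal at the default design size (~0.85–0.90 empirically).
- Moran's I significance is assessed only by permutation in the tests; no
  analytical variance is implemented.
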