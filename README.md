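# cyclexpo

Cyclists riding in heavily polluted megacities are exposed simultaneously to
road-traffic noise and nitrogen dioxide (NO₂), and — because cycling raises
minute ventilation — they inhale far more pollutant per minute than
pedestrians. `cyclexpo` is a Python package for the full analysis chain used
in mobile-sensing exposure studies of this kind:

1. **Simulation** of a typed road network, 1 Hz GPS rides and per-minute
   sensor streams (noise L_Aeq,1min, NO₂, humidity, wind, minute
   ventilation) with a known generating truth;
2. **Segmentation** of merged GPS + sensor streams into one-minute trip
   segments, the analysis unit;
3. **Descriptive statistics** — percentiles, energy-scale decibel mean/SD,
   a within-trip temporal autocorrelation index, and distance-band Moran's I;
4. **GAMMAR exposure models** — generalized additive mixed models with a
   moving-average residual term — for noise, NO₂ and inhaled dose;
5. **Dose and hazard assessment** against WHO guideline values: noise dose,
   NO₂ intake thresholds and minutes-to-threshold curves by road type and
   location.

It is aimed at environmental-epidemiology and transport-health researchers
who want a tested, reproducible reference implementation of these methods —
with a synthetic-data generator that makes every stage testable without any
field data.

## The model

For each response (noise in dB(A), NO₂ in µg/m³, inhaled NO₂ in µg) the
one-minute segments are modelled as

    y_t = β₀ + x_tᵀβ + f(clock_t) + g(x_t, y_t) + b_day + b_participant + r_t
    r_t = e_t + θ₁ e_{t−1} + θ₂ e_{t−2} + θ₃ e_{t−3},   e_t ~ Student-t(ν)

with fixed effects x (time shares on five road classes relative to
residential streets, speed, slope, intersections crossed, and — for the NO₂
and inhalation models — humidity and wind), a centred time-of-day smooth f, a
centred 2-D spatial smooth g, crossed random intercepts for day and
participant, and an MA(3) residual process that resets at trip boundaries.
Estimation is iterated two-stage feasible GLS with Student-t IRLS; intervals
are Wald with a delete-one-trip jackknife covariance (see
`docs/methods.md`).

Supporting quantities:

- inhaled dose per minute: `I = (VE × 0.001) × NO₂` with VE in L/min;
- noise dose (% of a criterion exposure L_c over T_c, exchange-rate
  parameter q = 10 for the 3 dB rule):
  `D = (100/T_c) · Σᵢ Tᵢ · 10^((Lᵢ − L_c)/q)`;
- WHO-based intake thresholds: 200 µg/m³ × VE × 1 h → 180 µg (pedestrian,
  15 L/min) and 420 µg (cyclist, 35 L/min);
- noise criterion: 59.3 dB L_den over 24 h (configurable).

## Worked example

```python
from cyclexpo import (
    ModelSpec, build_design, crossings_table, default_scenario, fit_gammar,
    hazard_curves, summarize_exposure,
)
from cyclexpo.dose import field_percentile_locations
from cyclexpo.pipeline import simulate_study

scenario = default_scenario()          # generating truth
network, tracks, segments = simulate_study(
    scenario, seed=1, n_trips=15, minutes_per_trip=200,
)                                       # 3,000 one-minute segments

summary = summarize_exposure(segments)
print(summary.table.loc[["mean", "sd", "acf_k1"]].round(2))

m_noise = fit_gammar(build_design(segments, ModelSpec(response="noise_db")))
m_no2 = fit_gammar(build_design(segments, ModelSpec(response="no2_ugm3")))
e = m_no2.estimates["primary"]
print(f"primary-road NO2 effect: {e[0]:.2f} [{e[1]:.2f}, {e[2]:.2f}] ug/m3")
```

prints (energy-scale mean for noise; arithmetic for the others):

```
           noise_db  no2_ugm3  inhaled_ug
statistic
mean          80.47    214.46        7.38
sd             3.83     69.16        3.49
acf_k1         0.54      0.58        0.56
primary-road NO2 effect: 51.42 [43.97, 58.88] ug/m3
```

The interval covers the generating effect of 47.21 µg/m³: riding one minute
on a primary road instead of a residential street raises expected NO₂
exposure by ~47 µg/m³ under the default scenario. Hazard curves then convert
fitted exposure levels into cumulative doses:

```python
xs = [s.midpoint_xy[0] for s in segments]; ys = [s.midpoint_xy[1] for s in segments]
locations = field_percentile_locations(
    scenario.spatial_field["no2_ugm3"], scenario.extent,
    labels=("low", "moderate", "high"),
    bounds=(min(xs), min(ys), max(xs), max(ys)),
)
curves = hazard_curves(m_noise, m_no2, locations, ("residential", "primary"),
                       120, covariates={"humidity": 46.0, "wind": 9.0, "speed": 17.0})
print(crossings_table(curves).head(4).to_string(index=False))
```

```
location   road_type       response  threshold  crossing_min  value_60min  crossing_min_pedestrian_threshold
     low residential noise_dose_pct      100.0          35.2   170.270308                                NaN
     low residential  no2_intake_ug      420.0          71.7   351.232700                               30.7
     low     primary noise_dose_pct      100.0          16.0   376.122649                                NaN
     low     primary  no2_intake_ug      420.0          54.9   459.221799                               23.5
```

Reading the first row: cycling in a low-exposure area on residential streets,
the daily noise-dose criterion is passed after 35.2 minutes, and after one
hour the rider has accumulated a 170% noise dose and 351 µg of inhaled NO₂
(the pedestrian-rate threshold of 180 µg would already be passed at
30.7 min).

A command-line interface wraps the same stages:

```bash
cyclexpo run --seed 1 --out runs/demo          # full pipeline + manifest
cyclexpo simulate --seed 1 --out runs/sim      # network + segments CSV
cyclexpo describe runs/sim/segments.csv --out summary.csv
cyclexpo fit runs/sim/segments.csv --out coefficients.csv
cyclexpo hazard runs/sim/segments.csv --out runs/hazard --plot
```

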