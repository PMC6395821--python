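# thermoselect

Resource-selection analysis of heat-driven habitat choice in mountain
wildlife, with climate-change projection of future selection maps.

Heat-sensitive endotherms such as the Alpine ibex (*Capra ibex*) trade
forage quality for cooler terrain as temperatures rise. `thermoselect`
packages the full analysis chain used to quantify that trade-off from
direct-observation data and to project it under warming scenarios:

- a **synthetic-world generator** (alpine-valley DEM, NDVI, trails, safe
  areas, hourly station weather, a temperature-logger network, and grouped
  animal observations drawn from a *known* selection function), so every
  stage is verifiable by parameter recovery;
- **thermal-field interpolation** from loggers + station to per-pixel
  hourly and maximum-daily temperature;
- the **two-scale used/available design** (population-level 100% MCP and
  per-observation mobility buffers, 1 used : k available strata, table-wide
  standardization, availability-ratio sensitivity analysis);
- **covariate screening** (Pearson |r| ≤ 0.7, VIF ≤ 3, random-forest
  importance, backward step-AIC with a marginality constraint);
- the **RSF core**: used/available logistic estimation (fixed-effects by
  default, Laplace random intercepts behind a flag), AIC comparison of the
  max-daily vs hourly temperature hypotheses, latent-scale marginal and
  conditional R²;
- **area-adjusted k-fold validation** (Boyce method: decile bins of
  availability, Spearman ρ per withheld fold);
- **climate-delta projection**: per-ensemble-member ΔT shifts of the
  max-daily field, member-wise RSF maps with ensemble mean/SD summaries,
  range-retention fractions and elevation-shift profiles.

## The model

Selection is modelled as an exponential resource selection function over
standardized covariates z₁…zₙ,

    w(x) = exp(β₁z₁ + β₂z₂ + … + βₙzₙ),

with β estimated by logistic regression of used (1) vs available (0)
points; the intercept is dropped at scoring time. Quadratic terms (e.g.
maximum daily temperature²) give concave responses whose vertex
z\* = −β₁/(2β₂) is the preferred condition; two- and three-way products
(e.g. cos-aspect × cos-wind-direction × wind speed) encode interactive
selection. The thermal field is linear in station temperature, the
elevation offset (lapse rate, ≈ −6.5 °C/km) and hydro-geographic sector.
Projection adds a scenario shift ΔT to the max-daily field, re-standardizes
with the *fitting* scaling parameters, and re-evaluates w pixel-wise for
every ensemble member before averaging.

## Worked example

```python
import thermoselect as ts
from thermoselect.rsf import ModelSpec, RSFModel, compare_aic

stack = ts.generate_landscape(ts.LandscapeConfig(nrows=80, ncols=80, seed=1))
weather = ts.generate_weather(ts.WeatherConfig(n_days=80, seed=2))
truth = ts.TrueRSF(
    ModelSpec((("temp",), ("temp", "temp"), ("ndvi",), ("slope",)),
              temperature="max_daily"),
    [0.6, -0.4, 0.5, -0.3],
)
obs = ts.simulate_observations(stack, weather, truth, ts.ThermalTruth(),
                               n_individuals=50, n_days=60, seed=3)
net = ts.generate_logger_data(stack, weather, noise_sd=0.5, n_loggers=17, seed=4)
thermal = ts.fit_thermal_model(net, weather)
domain = ts.availability_domain(obs, "large")
table = ts.sample_available(obs, domain, 15, stack, seed=5)
table = ts.attach_covariates(table, stack, thermal, weather)
table, scaling = ts.standardize(table)
fit = RSFModel(table, truth.spec, scaling).fit()
alt = RSFModel(table, truth.spec.with_temperature("hourly"), scaling).fit()
```

Output of the surrounding script:

```
observations: 1043 sightings of 50 individuals in 401 groups
thermal model: lapse = -0.00651 degC/m, residual SD = 0.500 degC
delta AIC (hourly - max-daily): 11.01
marginal R2 = 0.19, conditional R2 = 0.19
                beta     SE       z      p
t_max_daily    0.147  0.049   2.999  0.003
t_max_daily^2 -0.112  0.036  -3.130  0.002
ndvi           0.574  0.043  13.448  0.000
slope         -0.372  0.027 -13.880  0.000
fold rho: [1.0, 0.842, 0.939, 0.855, 0.976]
```

Reading it: the generator's lapse (−0.0065 °C/m) and logger noise
(0.5 °C) are recovered exactly; the positive ΔAIC says the data —
generated under max-daily-driven selection — prefer the max-daily model
over the hourly alternative; the concave temperature response (negative
quadratic) and the NDVI/slope coefficients recover the planted selection
pattern on the design's standardized scale; the high per-fold Spearman ρ
says withheld used points concentrate in high-score bins.

A single YAML config runs the whole chain from the shell and writes every
intermediate plus a hashed run manifest:

```
thermoselect run-all config.yaml
```

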