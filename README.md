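# airfusion

Bayesian geostatistical fusion of point NO₂ measurements with gridded
dispersion-model output, for fine-scale air-pollution exposure surfaces
with calibrated uncertainty.

## The problem

Epidemiological studies of air pollution and health need concentrations at
fine spatial resolution, but the networks that measure NO₂ are sparse:
automatic chemiluminescence monitors are few and costly, and the much more
abundant passive diffusion tubes still leave most of a region unobserved.
Atmospheric dispersion models (such as the UK's Pollution Climate Mapping
background surfaces) cover every 1 km grid cell but are uncalibrated and
carry no uncertainty. `airfusion` implements a *fusion* (downscaler) model
that regresses the point measurements — monitors and tubes together — on
the gridded model output, so the abundant-but-imperfect and
complete-but-biased data sources correct each other.

## The model

For log-transformed annual-mean concentrations `Y(s_i)` at `m` sites:

    Y(s_i) ~ N( z(s_i)'α + φ(s_i),  ν²σ² )          i = 1..m
    φ      ~ N( 0, σ² Σ(ρ) ),   Σ(ρ) = exp(−ρ D)

where `z(s_i)` holds an intercept, the natural log of the modelled
background concentration, an optional monitor/tube indicator, local
environment dummies (kerbside reference) and optional spatially varying
slope terms `log modelled × easting/northing`. `D` is the matrix of
pairwise distances (km), `ρ` the exponential decay (effective range
≈ 3/ρ km), `σ²` the spatial variance and `ν²` the noise-to-signal ratio,
so the nugget is `ν²σ²`.

Priors: `α ~ N(0, 1000·I)`, `σ² ~ InvGamma(0.001, 0.001)`,
`ν² ~ Uniform(0,1)`, and a **discrete** uniform prior over 50 candidate
decays, so every correlation matrix the chain can visit is factorized
exactly once up front — 50 factorizations per fit, regardless of chain
length. Inference is a Gibbs scan (`α, φ, σ², ρ` exactly conjugate or
enumerable) with a logit-scale random-walk Metropolis step for `ν²`.
Prediction at new locations is two-step Bayesian kriging per retained draw:
an exact conditional-Gaussian draw of `φ*` given `φ`, then
`Y* ~ N(z*'α + φ*, ν²σ²)`. Validation is leave-one-out cross-validation
with log-scale bias, RMSPE and 95%-interval coverage, plus plug-in REML,
non-spatial OLS and adjusted-dispersion-model comparators.

Because the motivating monitoring data are not redistributable, the package
ships a synthetic-data generator that reproduces their structure (246 sites
= 230 tubes + 16 monitors, environment mix, co-located monitor–tube pairs,
preferential siting, a smooth modelled-background surface) and draws
observations exactly from the model above.

## Worked example

```python
import airfusion as af

cfg = af.SyntheticConfig(extent_m=(0, 10_000, 0, 10_000),
                         n_tubes=52, n_monitors=8, n_colocated=4, seed=3)
sites, grid = af.generate_dataset(cfg)
fit = af.fit_fusion_model(sites, af.CovariateSpec(include_source=True),
                          n_burn=500, n_keep=1000, seed=1)
for name, s in fit.posterior.summary().items():
    print(f"{name:>18s} {s['median']:8.3f} ({s['lo95']:.3f}, {s['hi95']:.3f})")
```

prints (generating values: intercept 1.900, log_modelled 0.594, monitor
0.125, σ² 0.057, ν² 0.232, ρ 12.852):

```
         intercept     1.991  (1.191, 2.428)
      log_modelled     0.537  (0.332, 0.904)
           monitor     0.144  (0.040, 0.247)
          roadside    -0.296  (-0.432, -0.131)
  urban_background    -0.571  (-0.690, -0.437)
             rural    -0.909  (-1.108, -0.750)
           special    -0.257  (-0.559, 0.200)
            sigma2     0.055  (0.035, 0.081)
               nu2     0.035  (0.006, 0.340)
               rho    13.472  (2.748, 51.709)
```

Every 95% credible interval covers its generating value; the decay and
noise-to-signal ratio are weakly identified at 60 sites, which the wide
intervals report honestly. Predicting the grid
(`af.predict_grid(fit, grid, seed=2)`) then gives per-cell posterior
medians and intervals — urban cells around 14.6 µg/m³ versus 8.5 µg/m³ for
rural ones on this region, with log-scale standard errors near 0.26.

The `examples/` directory has one short script per capability
(`simulate_region.py`, `fit_and_summarize.py`, `predict_surface.py`,
`cross_validate.py`), and the same stages are available from a thin CLI:

```bash
airfusion simulate --seed 1 --out data/
airfusion fit --sites data/sites.csv --seed 1 --out posterior.npz
airfusion predict --sites data/sites.csv --grid data/grid.csv --seed 1 --out preds.csv
airfusion validate --sites data/sites.csv --method ols --seed 1 --out val.csv
airfusion run --config config.yaml
```

File schemas: sites CSV columns `site_id, easting_m, northing_m, source
(monitor|tube), environment (kerbside|roadside|urban_background|rural|
special), pcm_no2_ugm3, no2_ugm3`; grid CSV columns `cell_id, easting_m,
northing_m, pcm_no2_ugm3, urban`. Coordinates are metres; concentrations
µg/m³.

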