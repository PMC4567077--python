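# Methods

This note documents the statistical model implemented in `airfusion`, the
algorithms behind each stage, the synthetic-data generator that stands in
for the (non-redistributable) motivating monitoring data, and the numerical
and design choices a maintainer should know about.

## Model

Observations are annual-mean NO₂ concentrations at `m` point locations,
log-transformed (they are positive and right-skewed). With `Y` the
log-concentration vector, `Z` an `m × p` covariate matrix and `φ` a spatial
random effect:

    Y | α, φ, σ², ν²  ~  N(Zα + φ, ν²σ² I)
    φ | σ², ρ         ~  N(0, σ² Σ(ρ)),    Σ(ρ)_ij = exp(−ρ ‖s_i − s_j‖)

Distances are Euclidean in kilometres; `ρ` is a decay per km (effective
correlation range ≈ 3/ρ km); `σ²` is the spatial variance; `ν² ∈ (0,1)` is
the noise-to-signal ratio, making the nugget `ν²σ²` — the prior restriction
to (0,1) encodes the expectation that micro-scale/measurement noise is
smaller than the spatial signal.

Covariates are declarative (`CovariateSpec`): intercept (always), natural
log of the gridded dispersion-model background value, a monitor/tube
indicator (tube reference), local-environment dummies (kerbside reference;
columns only for levels actually observed, so the design never contains a
constant column besides the intercept), and optional spatially varying
slopes `log_modelled × easting` and `log_modelled × northing`. Interaction
coordinates are centred at the training-site centroid and scaled to units
of 10 km; the centering constants are stored in the fitted design so
prediction locations get the identical transform. Raw metre coordinates
(~10⁵) would otherwise make the cross-product matrix ill-conditioned.

## Priors and posterior computation

* `α ~ N(0, v I)` with `v = 1000` (weakly informative; the scale of log
  concentrations is ~1–4).
* `σ² ~ InvGamma(a, b)`, `a = b = 0.001`.
* `ν² ~ Uniform(0, 1)`.
* `ρ ~ DiscreteUniform(ρ₁ … ρ_r)`, `r = 50` by default.

The discrete decay prior is the computational backbone: all `r` correlation
matrices, inverses and log-determinants are Cholesky-factorized once and
cached, so the sampler never factorizes `Σ` again. The cache counts its
factorizations and the count is exposed on the fitted posterior — exactly
`r` per fitted dataset, independent of chain length.

One systematic Gibbs scan per iteration, in the order α → φ → σ² → ν² → ρ
(any fixed order is valid; this one maximizes reuse of the cached
`Σ(ρ)⁻¹`):

* **α**: conjugate Gaussian, precision `Z'Z/(ν²σ²) + I/v`.
* **φ**: conjugate Gaussian, precision `σ⁻²(Σ(ρ)⁻¹ + ν⁻²I)`, mean solving
  that precision against `(Y − Zα)/(ν²σ²)`.
* **σ²**: inverse gamma with shape `a + m` — both the nugget likelihood and
  the spatial prior have variances proportional to σ², so each contributes
  m/2 — and scale `b + ½[φ'Σ(ρ)⁻¹φ + ν⁻²‖Y − Zα − φ‖²]`.
* **ν²**: random-walk Metropolis on the logit scale (the Jacobian
  `ν²(1−ν²)` is included). The step size starts at 1.0 and is nudged every
  25 burn-in iterations by `exp(rate − 0.35)` toward a 20–50% acceptance
  rate, then frozen for the retained phase so detailed balance holds.
* **ρ**: exact categorical draw from
  `p(ρ_k) ∝ exp(−½ log|Σ(ρ_k)| − φ'Σ(ρ_k)⁻¹φ/(2σ²))`, computed with a
  max-shift (log-sum-exp) guard.

Defaults: 500 burn-in + 1,000 retained draws for cross-validation fits,
500 + 2,000 for full-scale fits; single chain. A crude Geweke-style z-score
(early 10% vs late 50% means, iid standard errors) is reported as a
stationarity *flag*, not a calibrated test. The chain aborts with a state
dump if σ² diverges.

The default decay grid is 50 geometrically spaced values chosen so the
effective range 3/ρ spans 0.005× to 2× the maximum inter-site distance.
The wide short-range end is deliberate: with co-located instrument pairs in
the data, correlation that is appreciable only at near-coincident sites is
a real feature, and a narrower grid could not represent a decay of order
10/km on a ~25 km domain.

## Prediction

Two-step Bayesian kriging, per retained draw. Step one draws the random
effects at the `N` prediction locations from the exact conditional
multivariate normal,

    E[φ*|φ]   = C Σ_obs(ρ)⁻¹ φ
    Var[φ*|φ] = σ² [ Σ_pred(ρ) − C Σ_obs(ρ)⁻¹ C' ]

with `C` the `N × m` cross-correlation matrix — the standard
conditional-Gaussian (ordinary-kriging) form. These formulas interpolate
exactly (zero variance at an observation site) and fall back to the prior
(mean 0, variance σ²) far away. Step two adds the covariate mean and
nugget: `Y* ~ N(Z*α + φ*, ν²σ²)`. Grid cells are processed in batches
(default 200) so the `N × N` conditional covariance stays small; batches
are conditionally independent given `φ`, so this loses nothing. Tiny
negative conditional-covariance eigenvalues from floating-point
cancellation are clipped to zero.

Per-location summaries are computed on the log scale — median, standard
deviation ("standard error" of the surface), central 95% interval — and
medians/interval endpoints are exponentiated to µg/m³, which is exact for
quantiles of a monotone transform.

For grid prediction every cell's design row forces the environment to
urban-background (urban flag set) or rural, and the source indicator to its
tube reference: a 1 km cell average is a background quantity, and roadside
increments are both averaged out at that scale and unrepresentative of
residential exposure.

## Comparators

* **REML**: restricted maximum likelihood for `Y ~ N(Zα, σ²[Σ(ρ) + ν²I])`,
  with σ² profiled in closed form, ν² optimized on the log scale per decay
  candidate (bounded in `[e⁻¹², e⁵]`; the ν² < 1 prior restriction is not
  imposed on this frequentist comparator) and a profile search over the
  same discrete ρ grid. Predictions are universal kriging with the
  estimated variance parameters treated as fixed and known — the point of
  this comparator is precisely that its intervals omit parameter
  uncertainty and are therefore narrower than the Bayesian ones.
* **OLS**: ordinary least squares on the log scale with t-based prediction
  intervals (statsmodels), ignoring spatial correlation entirely.
* **Adjusted dispersion baseline**: predicts log concentration by the log
  modelled value plus an OLS-fitted additive offset for roadside/kerbside
  sites — what one would do with the gridded model output alone.

## Validation

Leave-one-out cross-validation: each site is removed in turn, the model is
refitted on the remainder and the held-out site is predicted via the full
two-step procedure (point prediction = posterior median of `Y*`; interval
= central 95% of the `Y*` draws). Metrics, all on the log (modelling)
scale:

* bias = mean(prediction − observation),
* RMSPE = root mean square of those differences (so RMSPE² ≥ bias², an
  identity the tests enforce),
* coverage = % of closed 95% intervals containing the held-out value.

When a held-out site has a co-located twin, the twin stays in the training
set: sharing coordinates is a property of the network, not leakage of the
held-out measurement — and it is exactly why adding monitors to an already
co-located tube network adds little predictive information.

Folds whose design cannot be built (the held-out site carries a factor
level absent from the remaining data — possible for the rarest environment
classes at small m) are skipped with a warning; more than 5% skipped folds
aborts the run. The data-source comparison (fit on monitors only / tubes
only / both, predict every site) fits each subset once for the
out-of-subset sites and leave-one-out refits for subset members.

## Synthetic-data generator

The generator emulates the structure of the motivating study region:

* a regular 1 km grid whose log modelled-background surface is a smooth
  Gaussian random field (squared-exponential kernel, 5 km range, sd 0.25 on
  the log scale) around a 4.8 µg/m³ rural baseline, plus a Gaussian "urban
  bump" of 0.9 log units centred on a synthetic city; cells within the
  urban radius (default 35% of the shorter extent side) are flagged urban;
* a network of diffusion tubes and automatic monitors placed with
  probability proportional to the cell's modelled value (preferential,
  compliance-driven siting), with a configurable number of monitor–tube
  co-located pairs sharing exact coordinates;
* environment labels drawn multinomially with probabilities 142/34/8/60/2
  out of 246 (roadside/kerbside/special/urban-background/rural);
* observations drawn *exactly* from the fusion model above, with generative
  parameters defaulting to the fitted study's posterior medians: intercept
  1.900, log modelled 0.594, monitor 0.125, roadside −0.150, rural −1.021,
  special −0.390, urban background −0.531, σ² = 0.057, ν² = 0.232,
  ρ = 12.852 per km. The realized `φ` and noiseless log mean are retained
  as columns for oracle checks.

Full scale is 230 tubes + 16 monitors (8 co-located) on a 20 km × 20 km
extent — the study's region area and network size. The scaled replicate
used by the faster experiments keeps the same site density and composition
at a quarter of the area: 52 tubes + 8 monitors (4 co-located) on
10 km × 10 km.

What the generator does **not** emulate: the real road network and
geography (sites are preferentially urban but not literally roadside), the
dispersion model's own biases (the synthetic surface is exchangeable with
the truth up to the regression), instrument-specific error structure
(tubes and monitors share the nugget; the monitor offset is purely a mean
shift), and temporal structure. Passing tests therefore demonstrate that
the machinery is correct and calibrated *under the model's own
assumptions*; they cannot certify performance on real networks where the
model is misspecified.

## Numerical choices

* **Units**: coordinates are metres in all tables and files, divided by
  1000 at one boundary (the distance-matrix builder). The decay is per km —
  a posterior median near 13/km gives a ~230 m effective range, the scale
  at which co-located and same-street instruments correlate.
* **Duplicated coordinates**: co-located pairs keep identical coordinates
  in the tables, and a deterministic 1 m jitter (cycling E/N/W/S) is
  applied before any correlation matrix is formed, since `exp(−ρD)` is
  singular at zero distance.
* **Concentrations of exactly zero** are rejected at parse time rather than
  offset — the log transform is part of the model.
* **Conditional covariance** factorization falls back from Cholesky to an
  eigendecomposition with clipping at zero; eigenvalues below −10⁻⁶ raise.
* **Tie-breaks**: the discrete ρ draw uses inverse-CDF sampling on the
  normalized masses; ρ candidates are strictly increasing by construction.

## Scaled experiment sizes

The statistical acceptance experiments run at desk scale, chosen as the
package's own defaults: calibration uses 5 replicate 60-site networks with
a 1,500-iteration chain per leave-one-out fold (~300 MCMC fits);
parameter recovery uses 20 full-scale (m = 246) fits with 2,000 retained
draws; the directional comparisons (spatial vs non-spatial, fusion vs
adjusted baseline, monitors-only vs tubes-only) use 10 replicates each.
The spatial-vs-non-spatial comparison generates its replicates with a 2 km
correlation range (ρ = 1.5/km, other parameters unchanged): a comparison
of spatial against non-spatial prediction is informative only where the
correlation range is comparable to the inter-site spacing, whereas at the
fitted 230 m range a 60-site network is correlated essentially only within
its co-located pairs. The data-source comparison runs with the intercept + log-modelled
covariate set: with only 8–16 monitors, multinomial environment labels
frequently leave whole levels unobserved in the monitors-only training
set, which would turn the comparison into a test of factor-level overlap
rather than of the information content of each network.

## Known limitations

* A single chain with a heuristic stationarity flag; no multi-chain
  convergence machinery.
* The exponential kernel only — no Matérn smoothness parameter, no
  anisotropy.
* The decay grid is fixed before fitting; a true decay outside its span is
  mapped to the boundary.
* LOOCV refits the model m times; at full scale with long chains this is
  the dominant cost (it is embarrassingly parallel but implemented
  serially).
* REML prediction intervals use Gaussian quantiles with plug-in variance
  components, which is exactly the comparator's documented weakness.
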