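# Methods

`lgcpindex` implements a log-Gaussian Cox process (LGCP) analysis of
plankton-recorder style survey counts: per-tow larvae counts are Poisson
conditional on a latent Gaussian log-intensity with separable space–time
correlation, random yearly levels and per-sample noise, plus fixed seasonal
and catchability effects.  The model is fitted by maximum likelihood with the
Laplace approximation, and the fitted posterior is turned into intensity
maps and a yearly abundance index with uncertainty.  A companion module
backtracks passive particles through velocity fields to quantify how far
larvae drift between spawning and capture.

## Model

For sample *i* in grid cell *x*, year *y*, day of year *d*, hour *h* and
thermocline depth *t*:

```
N_i | eta_i ~ Poisson(exp(eta_i))
eta_i = c + F(x_i, y_i) + U(y_i) + p_spawn(d_i) + p_thc(t_i) [+ mu(h_i)] + eps_i
```

* `F` — mean-zero Gaussian space–time field over cells × years with separable
  exponential covariance `sigma^2 * exp(-alpha * dx_km) * exp(-beta * dt_yr)`;
  `dx` is the great-circle distance between cell centroids in km, `dt` the
  integer year lag.
* `U` — mean-zero yearly level with covariance `sigma_y^2 * exp(-beta * dt)`.
* `eps` — iid per-sample nugget, variance `sigma0^2`, capturing small-scale
  sampling variability (it makes the counts Poisson–log-normal, hence
  overdispersed: Var = m + m^2 (exp(sigma0^2) - 1)).
* `p_spawn(d) = a1*d - a2*d^2` — the seasonal curve; a concave quadratic in
  the log, i.e. a Gaussian-shaped season with peak at `a1 / (2 a2)`.
* `p_thc(t) = b1*t - b2*t^2` — thermocline-depth catchability: the recorder
  samples at a fixed ~7 m depth, so gear efficiency depends on where the
  larvae sit relative to the thermocline.  Quadratics are parameterised with
  `a1, a2 > 0` so positive coefficients give peaked curves.
* `mu(h)` — optional hour-of-day offsets (diurnal migration), constrained to
  sum to zero for identifiability against the global intercept `c`; disabled
  by default (the effect is testable by a 23-df likelihood-ratio test).
* an optional late-period offset on the year-level mean supports the
  early/late period-shift test; intermediate years carry no offset and follow
  the latent level.

Day-of-year and thermocline covariates are centred and scaled internally for
conditioning (day: (d-183)/100; thermocline: (t-30)/10); reported
coefficients and their standard errors are transformed back to the raw scale.

Missing thermocline values (fully mixed column) default to the "deep" policy:
they are treated as a column deeper than the catchability range (60 m);
a strict policy that raises instead is available.  This choice is a package
decision — how the original survey analysis handled mixed columns is not
documented.

## Inference

The latent vector `u = (F, U, eps)` is integrated out with the Laplace
approximation: `-log L(theta) = f(u*) + 0.5 log det H - (dim(u)/2) log 2 pi`,
where `f` is the joint negative log density, `u*` its minimiser and
`H = Q + A' W A` the joint Hessian (`Q` prior precision, `W = diag(exp(eta))`,
`A` the sparse incidence of samples onto latents).  Numerical choices:

* Inner problem: the joint density is strictly convex in `u`; Newton
  iteration with step halving, gradient tolerance `1e-8` (with a
  relative floor `1e-10 |f|` and stall detection so the criterion is
  attainable at double precision), at most 100 iterations.
* The nugget block of `H` is diagonal and is eliminated analytically
  (Schur complement), so each Newton step factorises only the
  (cells·years + years)-dimensional reduced Hessian; the field block of `Q`
  is built from Kronecker factors of the small spatial and temporal
  correlation matrices.  A dense brute-force path
  (`lgcpindex._reference.laplace_nll_dense`) with no Kronecker shortcuts and
  no elimination exists purely as an oracle; tests require agreement to
  1e-8.
* Correlation matrices get `1e-8` jitter on the diagonal before Cholesky.
* Outer optimisation: L-BFGS-B on transformed parameters (log variances, log
  decay rates; fixed effects on the centred/scaled design), with the exact
  analytic gradient of the Laplace objective, including the
  implicit-function terms through the latent mode and the curvature
  (`0.5 tr(H^{-1} dH)`) terms.  The gradient is verified against central
  finite differences in the test suite.  Bounds keep log variances in
  [-12, 6] and decay rates in sensible ranges; relative function tolerance
  1e-10, gradient tolerance 1e-6.
* Standard errors: finite differences of the analytic gradient give the
  outer Hessian; parameters that finish on an active bound (typically a
  variance collapsing to zero) are excluded from the inversion, since the
  likelihood is one-sided there and including them corrupts every SE.
* Poisson-regression (IRLS) starting values for the fixed effects.
* Cells and years without samples remain in the latent field; Gaussian
  marginalisation is exact, so they are integrated out consistently.
* A Gaussian-observation family is built in as a validation gauge: with
  Gaussian observations the Laplace approximation is exact and must equal
  the closed-form marginal likelihood (tested); the 1-d Poisson case is
  checked against 61-node Gauss–Hermite quadrature.
* `sigma_y^2` can be tied to `sigma^2` (`tie_sigma_y`): the published
  parameter table prints only two variances, and whether the year level had
  its own variance is ambiguous; the default keeps it free.

## Posterior products

* **Posterior latents.**  The Laplace-Gaussian posterior of (F, U) has mean
  `u*` and covariance `S^{-1}` (the reduced Hessian inverse).  With no data
  this reproduces the prior exactly (tested).
* **Intensity maps.**  Per cell-year, `E[exp(eta)] = exp(m + v/2)` with m, v
  the posterior mean and variance including intercept, year level and the
  seasonal term at a chosen day (or integrated over days 1–365 by direct
  summation).  Catchability terms are held at their reference value — the
  maximum of the fitted catchability curve — because they describe
  observation efficiency, not abundance; this is a package decision.
* **Annual index.**  `index_y = sum_cells area_c * E[exp(eta_cy)]`, seasonally
  integrated, with spherical (cos-latitude) cell areas in km².  The 95%
  interval comes from seeded Monte-Carlo draws of the Laplace posterior
  (default 1000) propagated through the same sum — the exp-transformed sum is
  skewed, so the delta method is avoided.  Adding a constant to the intercept
  scales index and interval exactly (tested equivariance).
* **Period-shift test.**  The reduced model (no offset) is fitted first and
  the full model is warm-started from its optimum with offset 0, so the
  nesting inequality holds numerically; the statistic `2*(nll_red - nll_full)`
  is referred to chi-square(1).

## Synthetic data

The generator draws from exactly the model above: a seeded design (uniform
positions or 10-nautical-mile-spaced transects mimicking tow segmentation;
days uniform on 60–300, the surveyed season; hours uniform), a smooth monthly
thermocline field (seasonal sinusoid shallowest in late summer, south–north
gradient, smooth harmonic noise, clipped to 5–80 m, optional masked
mixed-column boxes) on a 0.1° × 1/6° grid, Kronecker-square-root field draws,
and Poisson counts.  Everything is reproducible from a single root seed.

Default truth parameters are the published survey estimates
(`sigma0^2 = 2.36`, `sigma^2 = 6.43`, `log alpha = -5.45`, `log beta = -1.22`,
seasonal 2.41e-1 / 6.21e-4, thermocline 8.33e-2 / 2.71e-3).  Two quantities
are not printed by that fit and are package defaults: the year-level variance
(`sigma_y^2 = 1.0`, a moderate yearly wobble) and the intercept
(`-23.0`, chosen once so that a desk-scale survey of 3000 samples yields a
few hundred positive tows — enough information for interior maximum-likelihood
estimates, comparable in spirit to the real survey's 4642 positives at 43×
the sample count; with a much lower mean the desk-scale likelihood for the
decay parameters degenerates).

What the generator does *not* emulate: the real survey's uneven route
pattern and effort drift, ship-speed and mesh-clogging effects, taxonomic
error, and real hydrography.  Passing recovery tests therefore demonstrate
correctness of the estimator under the model's own assumptions at desk
scale, not robustness to the field data's known quirks.

## Simulation studies (test suite scales)

* **Recovery** (acceptance): 8×8 cells of 0.3°×0.6°, 20 years, 3000 samples,
  published truth; 20 seeded replicates; `log alpha`, `log beta` and the
  seasonal coefficients must fall within ±2 reported SE of truth in ≥90% of
  replicates.  Wald intervals for spatial decay parameters are known to sit
  slightly below nominal coverage at small domain sizes, so this check sits
  near its boundary by construction.
* **Period-shift power and type-I error**: these run under a dedicated
  low-nuisance configuration (`sigma^2 = 0.05`, `sigma_y^2 = 0.02`,
  `sigma0^2 = 1`) designed a priori from an information calculation: at an
  8×8-cell desk domain the mean inter-cell spatial correlation under the
  published decay (~0.5) makes the spatial mean of the field an extra
  year-level process with variance ~3, so a log(4) period contrast is
  statistically confounded with latent variability regardless of sample
  size — no test could detect it.  The low-variance configuration isolates
  the shift signal and verifies the test machinery: power uses 4×4 cells,
  16 years, ~1500 samples, a true 4-fold drop, 20 replicates at the 0.1%
  level; type-I uses 100 cheap replicates (2×2 cells, 10 years, 400
  samples) at the 5% level with a binomial acceptance band.
* The hour-effect LR check runs at a deliberately tiny scale (2×2 cells,
  4 years) with a strong diurnal pattern; it checks detection and the
  nominal level, not a power curve.

## Backtracking

Particles are released at observation positions and advected backwards
(velocity negated) for a configurable duration — default 10 days, the
package's spawn-to-capture estimate: 6.7 days median egg duration plus
(4.8 mm − 3 mm) / 0.75 mm d⁻¹ ≈ 2.4 days of larval growth, 9.1 rounded up.
Integration is fixed-step RK4 (default 1 h) on latitude/longitude with the
sphere's metric; gridded fields are interpolated bilinearly in space and
linearly in time; analytic fields (still, uniform, solid rotation, single
gyre) serve as fixtures with known trajectories.  The solid-rotation field
is defined so that orbits are exact circles in (lat, lon·cos lat0), making
closed-orbit and convergence-order checks exact up to integrator error
(observed order ≈ 4).  Optional random-walk mixing (seeded) stands in for
turbulent dispersion and is off by default; no ontogenetic behaviour is
modelled.  Displacements are great-circle distances capture-point to
end-point; the per-observation median over particles is pooled across
observations into an ECDF, and quantiles use the inverted-CDF
(order-statistic) convention so "90% drifted less than X km" statements read
directly off the ECDF.

## Known limitations

* The Laplace approximation is used throughout; no MCMC/INLA cross-check is
  provided beyond the Gaussian-gauge and quadrature oracles.
* Maximum-likelihood variance estimates can hit zero at desk scale
  (especially `sigma_y^2`, which is weakly identified against the spatially
  coherent field on small domains); such parameters are reported with SE 0
  at the boundary.
* The index is in relative units (larvae per standard sample volume × km²
  × season); only ratios across years are meaningful.
* Domain sizes beyond a few thousand cells·years would need sparse or
  low-rank factorisations that are not implemented.
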