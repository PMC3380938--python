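# lgcpindex

Log-Gaussian Cox process abundance indices for plankton-recorder survey data.

Towed continuous plankton recorders sample fish larvae along shipping routes
for decades, producing long, sparse, patchy count series.  Turning those
counts into a defensible spawning-abundance time series requires a model
that handles spatial and temporal autocorrelation, enormous small-scale
sampling noise, uneven effort, and gear catchability that depends on the
vertical position of the larvae.  `lgcpindex` implements the log-Gaussian
Cox process approach to this problem for researchers in fisheries ecology
and survey statistics:

* counts are Poisson given a latent Gaussian log-intensity
  `eta = c + F(x, y) + U(y) + p_spawn(d) + p_thc(t) [+ mu(h)] + eps`,
  with a separable space–time field
  `Cov(F) = sigma^2 exp(-alpha dx_km - beta dt_yr)`, a correlated yearly
  level `U`, a per-sample nugget `eps` (variance `sigma0^2`), a quadratic
  (log-Gaussian) seasonal curve and a quadratic thermocline-depth
  catchability curve;
* the latent field is integrated out with the Laplace approximation and all
  structural parameters are estimated by maximum likelihood (exact analytic
  outer gradients, Kronecker-structured linear algebra);
* the fitted posterior yields intensity maps, a yearly spatially- and
  seasonally-integrated abundance index with Monte-Carlo 95% intervals, and
  likelihood-ratio tests (catchability effects; an early/late period shift
  in mean abundance);
* a backtracking module advects passive particles backwards through
  velocity fields to estimate how far larvae drift between spawning and
  capture, summarised as displacement ECDFs and quantiles;
* a synthetic-data module generates survey tables, thermocline fields and
  velocity fields from the model's own generative process, so the entire
  pipeline runs and is tested without any external data.

See `docs/methods.md` for the model, numerical choices and limitations.

## Worked example

```python
import numpy as np
from lgcpindex import (GridSpec, ModelParams, SimulationConfig,
                       simulate_dataset, LGCPModel, LGCPConfig, correlation_at)

grid = GridSpec(lat0=53.0, lon0=0.0, dlat=0.3, dlon=0.6, nlat=4, nlon=4)
truth = ModelParams(sigma0_sq=1.0, sigma_sq=0.8, sigma_y_sq=0.3,
                    log_alpha=-5.45, log_beta=-1.22, intercept=-23.0)
samples, latent, thermocline = simulate_dataset(
    SimulationConfig(grid=grid, years=(1998, 2005), samples_per_year=150,
                     params=truth, seed=1))

model = LGCPModel(samples, grid, years=(1998, 2005), config=LGCPConfig())
res = model.fit()
print(res.summary())
idx = res.annual_index(seed=1)
print(idx.round(1).to_string(index=False))
```

prints (abridged):

```
Log-Gaussian Cox process fit (Laplace-approximated ML)
  samples: 1200   cells: 16   years: 1998-2005
  negative log-likelihood: 1395.6805
  converged: True   max |gradient|: 2.11e-03

 parameter   estimate         se
 sigma0_sq    0.85622   0.093005
  sigma_sq    0.99929      1.792
 log_alpha    -5.3128     2.0445
sigma_y_sq   0.094848     1.7729
  log_beta   -0.57897    0.47537
  a_spawn1    0.21938   0.029736
  a_spawn2 0.00057464 6.7033e-05
    a_thc1   0.084502    0.11968
    a_thc2  0.0036534  0.0021521
 intercept    -19.771     4.1139

  seasonal peak day: 190.9
  catchability peak thermocline depth: 11.6 m
 year      index       lo95       hi95
 1998 34206681.4 26634183.0 43497150.9
 1999 15193990.6 11870666.2 19243178.9
 2000 20361217.4 15561260.7 26306692.1
 ...
 2005  9948131.9  7558467.7 13037254.8
```

At this deliberately small scale (16 cells, 8 years) the fixed effects are
recovered well — nugget variance 0.86 (truth 1.0), seasonal peak day 190.9
(the generating coefficients imply 194), catchability peak 11.6 m (truth
15.4 m) — while the decay rates carry the wide standard errors one expects
from so few cells and years (log alpha -5.31 ± 2.04 vs truth -5.45; the
acceptance-scale study with 64 cells and 20 years pins them down).  The
fitted decays translate into correlation summaries through
`correlation_at(res.params, 100, 0)` (here 0.61, spatial correlation at
100 km) and `correlation_at(res.params, 0, 1)` (here 0.57, adjacent-year
correlation); with the published decay estimates those evaluate to 0.65 and
0.74.  The index is in relative units (larvae per standard sample volume ×
km², integrated over cells and season); its year-to-year ratios are the
meaningful quantity.

A complete reproducible run — simulate, fit, index, period-shift test,
backtracking, report figures — is available from the shell:

```sh
lgcpindex run-all --config examples/demo.yaml --out demo_run
```

(`examples/demo.yaml` holds a `RunConfig`; see `lgcpindex/pipeline.py`).
Every run writes a `manifest.yaml` with the config hash and per-stage seeds.

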