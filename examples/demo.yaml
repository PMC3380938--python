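# Desk-scale end-to-end demo for `lgcpindex run-all --config examples/demo.yaml`
outdir: demo_run
seed: 42
grid:
  lat0: 53.0
  lon0: 0.0
  dlat: 0.3
  dlon: 0.6
  nlat: 4
  nlon: 4
years: [1998, 2005]
samples_per_year: 120
truth:
  sigma0_sq: 1.0
  sigma_sq: 0.8
  sigma_y_sq: 0.3
  log_alpha: -5.45
  log_beta: -1.22
  intercept: -23.0
index:
  n_draws: 500
shift_test:
  cut_before: 2001
  cut_after: 2002
backtrack:
  kind: gyre
  duration_days: 10.0
  n_particles: 100
  step_hours: 1.0
  amplitude: 0.1
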