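# Full-pipeline configuration consumed by `ltued run --config examples/run.yaml`.
out_dir: run
seed: 1
n_zcta: 392
top_k: 15
replace_mode: q2q5        # reset Q2-Q5 to the Q1 reference ("q2q4" spares Q5)
cov_type: HC1             # robust covariance flavor: HC0, HC1 or HC3
propensity_spec: fractional   # or "median-binary"
covariate_scale: percent  # regression covariates on the 0-100 scale ("fraction" divides by 100)
generator:
  population_range: [500, 14000]
  noise_fraction: 0.739
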