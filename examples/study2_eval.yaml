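# Evaluation run on a simulated early-enrollment cohort.
# Run with:  gestimpute evaluate --config examples/study2_eval.yaml
data:
  preset: study2        # or  data: {path: my_cohort.csv}
split:
  window: [13, 15]      # eligibility window, gestational weeks
  anchor: 14.0          # target: measurement closest to 14w0d is withheld
  n_test: 200
  min_measures: 2
grid:
  - {method: nearest}
  - {method: two_point}
  - {method: mixed, basis: {kind: polynomial, degree: 1}}
  - {method: mixed, basis: {kind: rcs, n_knots: 3}}
  - {method: gee, basis: {kind: rcs, n_knots: 3}, gee_mode: mean_residual}
  - {method: gee, basis: {kind: rcs, n_knots: 3}, gee_mode: nearest_residual}
variants:
  drop_t3: false        # drop training weights at >= 28 weeks
  log_scale: false      # ln(weight) before fitting, back-transformed after
bounds: [30, 120]       # plausible weight range, kg (inclusive)
out_dir: study2_eval_out
seed: 11
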