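# gestimpute

Imputation of **early-pregnancy weight** from repeated weight measurements
collected during antenatal care.

Quantifying gestational weight gain (GWG) needs an anchor weight at the end
of the first trimester (week 14 of gestation), but in many cohorts —
especially in low- and middle-income settings — most women first attend
antenatal care in the second or third trimester, so that weight was never
measured. `gestimpute` implements and compares four ways of filling it in
from the weights that *were* measured, for epidemiologists who need a
week-14 anchor before analysing GWG as exposure or outcome.

## Methods

With `W_ij` the j-th measured weight of woman i at gestational week `t_ij`,
and `g(·)` a time basis (linear/quadratic/cubic polynomial, or a restricted
cubic spline with 3–5 knots at percentiles of the training weeks), the
imputed weight at target week `t` (default 14.0) is:

1. **Nearest measure** — the training weight closest in time to `t`.
2. **Two-point arithmetic** — the line through the two closest measurements,
   evaluated at `t`.
3. **Mixed-effects model** — fit `W_ij = b_i + β_i′ g(t_ij) + ε_ij` with
   correlated subject-specific random intercept and slopes (unstructured
   covariance, REML); impute `b̂_i + β̂_i′ g(t)` using the empirical-Bayes
   (BLUP) subject effects.
4. **GEE marginal model** — fit `W_ij = γ + α′ g(t_ij) + e_ij` by
   generalized estimating equations; impute `γ̂ + α̂′ g(t) + ê_i`, where
   `ê_i` is the subject's mean training residual, or the residual nearest
   in time to `t`.

An evaluation protocol withholds, for each of 200 randomly sampled women
with a measurement in the 13–15-week window, the measurement closest to 14
weeks 0 days, imputes it with every configured method, and scores MAE (kg),
MSE (kg²), Spearman r and the proportion imputed within 2 kg. Sensitivity
switches drop third-trimester training weights, add maternal covariates
(age, gravidity, education), or log-transform weight before fitting.

Because the motivating cohort data are not publicly deposited, the package
ships a seeded synthetic-cohort generator with presets for the two
enrollment regimes: late enrollment (mean week 17.8 — imputation is
*extrapolation*) and early enrollment (mean week 10.0 — *interpolation*).

## Worked example

```python
from gestimpute import (BasisSpec, MethodSpec, SplitSpec, filter_implausible,
                        run_grid, simulate_cohort, study2_preset)

ds, _ = simulate_cohort(study2_preset(seed=11))     # 2131 women, early enrollment
ds, _ = filter_implausible(ds)                      # drop weights <30 or >120 kg
grid = [
    MethodSpec("nearest"),
    MethodSpec("two_point"),
    MethodSpec("mixed", basis=BasisSpec.rcs(3)),
    MethodSpec("gee", basis=BasisSpec.rcs(3), gee_mode="mean_residual"),
]
report = run_grid(ds, SplitSpec(n_test=200, seed=11), grid)
print(report.to_text())
```

prints

```
Imputation method                   MAE (kg)      MSE      r   <=2kg     n
--------------------------------------------------------------------------
nearest                                 1.94     6.09   0.98    59%   200
two_point                               1.80     6.11   0.97    64%   200
mixed[rcs3]                             1.50     3.60   0.99    72%   200
gee[rcs3,mean]                          1.59     4.09   0.98    70%   200
```

Lower MAE is better: the mixed-effects model wins because its random slope
captures each woman's own gain rate, which a marginal prediction plus a
constant residual offset cannot. The nearest measure carries the weight
gained between week 14 and the nearest visit; the two-point rule removes
that trend but amplifies measurement noise.

The `examples/` scripts walk through simulation, single-subject imputation
and the evaluation grid; `gestimpute simulate` and `gestimpute evaluate`
expose the same pipeline from the shell via a YAML run configuration
(see `examples/study2_eval.yaml`).

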