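# Methods

## Problem and scope

Gestational weight gain is usually anchored at the end of the first
trimester, taken here as week 14.0 of gestation (13–15 weeks is the
acceptance window). When a cohort lacks a measurement near week 14, the
anchor must be imputed from the woman's other antenatal weights. The
package implements four imputation rules, flexible time bases for the two
model-based rules, a withheld-measurement evaluation protocol, and a
synthetic cohort generator; it does not attempt pre-pregnancy weight, BMI,
multiple imputation, or information-criterion model selection.

## Models

**Mixed-effects model.** `W_ij = b_i + β_i′ g(t_ij) + ε_ij`, where the
subject-specific intercept `b_i` and slope vector `β_i` are jointly normal
with unrestricted means and an unstructured covariance, and `ε_ij` is
mean-zero normal noise. Estimation is restricted maximum likelihood via
statsmodels' `MixedLM`. By default the random-effects vector spans the
intercept and *every* column of `g(t)`; for 4–5-knot splines this is
deliberately ambitious and may fail to converge on sparse data — such
failures are reported as "N/A" grid cells, not crashes. A reduced structure
(random intercept + linear slope only, `random_structure="intercept_slope"`)
is available as a clearly-labelled escape hatch. The imputation is the
subject's empirical-Bayes curve `b̂_i + β̂_i′ g(t)`: fixed effects plus BLUP
deviations at the fitted variance components.

Two numerical choices matter here:

* *Random-effects scaling.* Intercept variance (kg², order 100) and
  slope variance (kg²/week², order 0.01) differ by four orders of
  magnitude, which stalls gradient optimizers. The random-effects columns
  are rescaled to unit SD for optimization and the BLUPs and covariance are
  mapped back afterwards; fitted curves are invariant. The optimizer order
  is lbfgs, then derivative-free Powell for small or near-degenerate
  samples.
* *BLUP computation.* Deviations are computed from the mixed-model-equations
  form `(Z_i′Z_i + σ̂² Ψ̂⁻¹) b = Z_i′(y_i − X_i β̂)` (eigen-guarded for
  singular Ψ̂), which is algebraically identical to the conditional-normal
  mean `Ψ̂ Z_i′ V_i⁻¹ (y_i − X_i β̂)` but remains stable as σ̂² → 0, so the
  noiseless limit degrades gracefully to per-subject least squares. Tests
  verify equality with the independently coded conditional-normal form to
  1e-6 kg.

**GEE marginal model.** `W_ij = γ + α′ g(t_ij) + e_ij` estimated by
generalized estimating equations (Gaussian family). The default working
correlation is unstructured with occasions indexed by the within-subject
rank of gestational week; because visit counts are unbalanced (1–10), the
available-pairs moment estimate can fail, in which case the fit falls back
to exchangeable with a warning (independence is also selectable; under it
the point estimates equal pooled OLS, an identity used as a test oracle).
Per-subject heterogeneity enters only at imputation time, through a
residual offset: the mean of the subject's training residuals, or the
residual nearest in time to the target (ties toward the earlier week).
Residuals are stored as `ê_ij = W_ij − γ̂ − α̂′ g(t_ij)` and are exactly
recomputable from the fit.

**Simple rules.** Nearest measure and two-point arithmetic use only the
subject's own series; all "closest" rules break ties toward the earlier
gestational week, deterministically.

## Time bases

`g(t)` is a raw polynomial (degree 1–3, no centering — conditioning is the
fitter's concern) or a restricted cubic spline in the truncated-power form
with Harrell's `(t_k − t_1)²` normalization, linear beyond the boundary
knots and C² everywhere. Coefficients are parametrization-specific but
fitted curves and imputations are not, and the tests assert the latter.
Knots sit at percentiles of the pooled training gestational weeks: either
equally spaced interior percentiles — quartiles {25,50,75}, quintiles
{20,40,60,80}, sextiles {16.7,…,83.3} — or a fixed scheme such as
{5,50,95}. Percentiles use linear interpolation between order statistics
(numpy's default); this convention is fixed and documented because knot
placement, and hence every downstream coefficient, depends on it.

## Evaluation protocol

Eligibility: ≥ 1 measurement inside the 13–15-week window and ≥ 2
measurements overall. A single seeded simple random sample of `n_test`
(default 200) eligible women forms the testing set; per woman the in-window
measurement closest to 14 weeks 0 days is withheld as ground truth. All
other measurements — including the test women's remaining visits — stay in
training, so model-based methods have a subject history to individualize
on. Tests assert conservation (train + targets = all) and no leakage on
every generated split.

Metrics per method: MAE in kg (with SD and IQR of absolute errors), MSE in
kg², Spearman correlation (average ranks for ties; reported missing for
constant vectors rather than zero), and the proportion within 2 kg,
boundary inclusive. One split is built per run and shared by all grid
cells. Sensitivity variants apply to training data only, in the fixed order
drop-third-trimester (cutoff 28.0 completed weeks, configurable — the
standard obstetric convention) → log-transform → fit; covariates enter the
model fits as fixed effects only. Log-scale imputations are back-transformed
by plain `exp` (no smearing correction) before scoring, so metrics are
always in kg.

Data cleaning: weights outside [30, 120] kg are implausible and dropped;
the bounds themselves survive (the exclusion rule is strictly-below /
strictly-above). Duplicate (subject, week) rows keep the first occurrence
with a warning.

## Synthetic cohorts

The generator emulates the two enrollment regimes the methods must handle:
`study1_preset` (enrollment GA ~ N(17.8, 4.4²) truncated to [4, 28] weeks,
baseline weight mean 59.7 SD 11.7 kg, delivery ~ N(39.5, 3.5²) on [28, 44],
n = 1472) and `study2_preset` (N(10.0, 2.4²) on [4, 14]; 55.6 SD 11.0 kg;
N(38.8, 2.7²); n = 2131). Visits recur at N(4.0, 0.5²)-week intervals
(≥ 1 week) until delivery; each follow-up visit is attended with
probability 0.75 (enrollment always), which places median visit counts near
5 and 6 for the two presets. The trajectory family is piecewise linear with
one changepoint — rate 0.10 kg/week before week 13, 0.45 kg/week after,
plus a subject-specific linear slope deviation (SD 0.10 kg/week) and
measurement noise (SD 1.5 kg). These trajectory, heterogeneity and noise
values are free parameters chosen once for physiological plausibility;
they are not estimates of any real cohort.

Baseline weight is drawn conditional on enrollment GA,
`B_i ~ N(μ_B + m(e_i) − m(μ_e), σ_B²)`, so all women follow one common
population curve and the subject intercept is independent of when she
enrolled. The alternative — drawing baseline weight independently of
enrollment time — would make later enrollees systematically lighter *for
their gestational age*, biasing slope estimation and contradicting the
observation that late- and early-enrolling cohorts report baseline weights
consistent with a single rising curve. Consequence: the marginal mean of
baseline weight equals the preset target exactly, while its marginal SD
exceeds the preset value slightly (by the variance of `m(e_i) + u_i e_i`,
about 2% for the late-enrollment preset).

The random slope is linear in t even though the mean curve is piecewise —
so a spline-basis mixed model is deliberately slightly misspecified,
mirroring reality and preventing trivially perfect recovery. What passing
tests on these cohorts do **not** show: robustness to informative missed
visits (attendance is independent of weight), covariate-dependent
trajectories, secular trends, or digit-preference in scale readings, none
of which the generator emulates.

## Problem sizes and design choices in the test suite

* The parameter-recovery check uses 20 replicate cohorts of 500 subjects
  with the two trajectory rates set equal (0.35 kg/week): under a linear
  basis a piecewise mean curve has no single generating slope, so equal
  rates make the recovery target well-defined.
* The qualitative-replication checks (mixed-effects most accurate; 
  interpolation more accurate than extrapolation) run the four methods with
  linear bases on full-size preset cohorts over 5 seeds; the ordering claim
  is about methods, not bases, and a ≥ 4/5-seed criterion absorbs
  Monte-Carlo variation.
* `scripts/acceptance.py` runs both presets at full size with linear and
  3-knot-spline bases, one seed, and reports MAEs plus the best
  mixed-effects cell's MSE / Spearman r / %-within-2-kg.

## Known limitations

* 4–5-knot mixed models with the full random-effects structure frequently
  fail to converge at realistic cohort sizes; this is reported honestly as
  an N/A cell. The reduced random structure is the practical alternative.
* Unstructured GEE falls back to exchangeable on small or very unbalanced
  cohorts; point estimates (and hence imputations) are barely affected, but
  the working-correlation label in the fit records which was used.
* Unknown subjects get the population curve with an explicit warning —
  useful in deployment, but outside the evaluation protocol, which
  guarantees every test subject has training history.
* The log-scale back-transform is naive `exp`; no smearing correction is
  applied.
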