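import warnings

import numpy as np
import pandas as pd
import pytest

from gestimpute import (
    BasisSpec,
    ImputationRequest,
    back_transform,
    fit_gee,
    fit_mixed,
    impute_gee,
    impute_mixed,
    impute_nearest,
    impute_two_point,
    transform_log,
)
from gestimpute.errors import NoDataError, ParameterError, PopulationOnlyWarning, UnknownSubjectError
from gestimpute.imputers import GEEFit

from conftest import make_dataset


def req(series_rows, target, sid="X"):
    return ImputationRequest(
        subject_id=sid,
        target_week=target,
        series=pd.DataFrame(series_rows, columns=["gest_week", "weight"]),
    )


class TestNearest:
    def test_unique_minimizer(self):
        assert impute_nearest(req([(16.0, 60.0), (20.0, 62.0)], 14.0)) == 60.0

    def test_tie_breaks_toward_earlier_week(self):
        assert impute_nearest(req([(13.0, 58.0), (15.0, 59.0)], 14.0)) == 58.0

    def test_singleton(self):
        assert impute_nearest(req([(18.0, 61.5)], 14.0)) == 61.5

    def test_empty_series(self):
        with pytest.raises(NoDataError):
            impute_nearest(req([], 14.0))

    def test_returns_an_observed_weight(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            rows = [(t, w) for t, w in zip(rng.uniform(5, 40, 6), rng.uniform(45, 90, 6))]
            out = impute_nearest(req(rows, float(rng.uniform(10, 20))))
            assert out in {w for _, w in rows}


class TestTwoPoint:
    def test_backward_extrapolation(self):
        assert impute_two_point(req([(16, 60.0), (20, 62.0)], 14)) == pytest.approx(59.0)

    def test_interior_interpolation(self):
        assert impute_two_point(req([(12, 57.0), (16, 59.0)], 14)) == pytest.approx(58.0)

    def test_target_at_data_point(self):
        assert impute_two_point(req([(14, 58.5), (20, 62.0)], 14)) == pytest.approx(58.5)

    def test_exact_for_affine_trajectory_any_visits(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a, b = rng.uniform(45, 70), rng.uniform(0.1, 0.6)
            times = np.sort(rng.uniform(5, 40, 5))
            rows = [(float(t), float(a + b * t)) for t in times]
            target = float(rng.uniform(8, 20))
            assert impute_two_point(req(rows, target)) == pytest.approx(a + b * target)

    def test_single_measurement_is_no_data(self):
        with pytest.raises(NoDataError):
            impute_two_point(req([(16, 60.0)], 14))


class TestOrderInvariance:
    def test_all_methods_ignore_row_order(self, common_slope_cohort):
        ds, _ = common_slope_cohort
        rows = [(13.0, 58.0), (15.0, 59.0), (22.0, 62.0), (30.0, 66.0)]
        fwd, rev = req(rows, 14.0), req(rows[::-1], 14.0)
        assert impute_nearest(fwd) == impute_nearest(rev)
        assert impute_two_point(fwd) == impute_two_point(rev)

        spec = BasisSpec.polynomial(1)
        shuffled = ds.to_frame().sample(frac=1, random_state=5)
        ds_shuf = make_dataset(list(shuffled.itertuples(index=False, name=None)))
        for fit_fn in (fit_mixed, fit_gee):
            f1, f2 = fit_fn(ds, spec), fit_fn(ds_shuf, spec)
            r = ImputationRequest.from_dataset(ds, "C2", 14.0)
            if fit_fn is fit_mixed:
                assert impute_mixed(f1, r) == pytest.approx(impute_mixed(f2, r), abs=1e-8)
            else:
                assert impute_gee(f1, r) == pytest.approx(impute_gee(f2, r), abs=1e-8)


class TestMixedModel:
    def test_noiseless_linear_reproduces_each_line(self, linear_cohort):
        ds, lines = linear_cohort
        fit = fit_mixed(ds, BasisSpec.polynomial(1))
        for sid, a, b in lines:
            for t in (14.0, 11.0, 25.0):
                r = ImputationRequest.from_dataset(ds, sid, t)
                assert impute_mixed(fit, r) == pytest.approx(a + b * t, abs=1e-6)

    def test_prediction_at_training_time_matches_observation(self, linear_cohort):
        ds, lines = linear_cohort
        fit = fit_mixed(ds, BasisSpec.polynomial(1))
        sid, a, b = lines[2]
        r = ImputationRequest.from_dataset(ds, sid, 16.0)
        assert impute_mixed(fit, r) == pytest.approx(a + b * 16.0, abs=1e-6)

    def test_single_subject_is_precondition_error(self):
        ds = make_dataset([("A", 10, 50.0), ("A", 20, 55.0), ("A", 30, 60.0)])
        with pytest.raises(ParameterError):
            fit_mixed(ds, BasisSpec.polynomial(1))

    def test_subject_effects_arithmetic(self, linear_cohort):
        ds, _ = linear_cohort
        fit = fit_mixed(ds, BasisSpec.polynomial(1))
        eff = fit.subject_effects("P1")  # (b_hat, beta_hat) totals
        r = ImputationRequest.from_dataset(ds, "P1", 14.0)
        assert impute_mixed(fit, r) == pytest.approx(eff[0] + eff[1] * 14.0, abs=1e-10)

    def test_unknown_subject_returns_population_with_flag(self, linear_cohort):
        ds, _ = linear_cohort
        fit = fit_mixed(ds, BasisSpec.polynomial(1))
        r = req([], 14.0, sid="GHOST")
        with pytest.warns(PopulationOnlyWarning):
            out = impute_mixed(fit, r)
        assert out == pytest.approx(fit.population_prediction(14.0))

    def test_shrinkage_toward_population_for_sparse_subject(self):
        # one subject contributes a single, strongly deviant measurement:
        # its BLUP prediction must deviate from the population curve by no
        # more than the observed deviation does (empirical-Bayes shrinkage)
        rng = np.random.default_rng(12)
        rows = []
        for i in range(30):
            a, b = 55 + rng.normal(0, 3), 0.4 + rng.normal(0, 0.05)
            for t in np.linspace(8, 36, 6):
                rows.append((f"S{i}", float(t), a + b * t + rng.normal(0, 1.0)))
        rows.append(("LONE", 20.0, 90.0))
        ds = make_dataset(rows)
        fit = fit_mixed(ds, BasisSpec.polynomial(1))
        r = ImputationRequest.from_dataset(ds, "LONE", 20.0)
        pop = fit.population_prediction(20.0)
        assert abs(impute_mixed(fit, r) - pop) <= abs(90.0 - pop)

    def test_random_effects_covariance_is_psd(self, linear_cohort):
        ds, _ = linear_cohort
        fit = fit_mixed(ds, BasisSpec.polynomial(1))
        assert fit.cov_re == pytest.approx(fit.cov_re.T)
        assert np.linalg.eigvalsh(fit.cov_re).min() >= -1e-8

    def test_parameter_recovery_on_simulated_cohort(self):
        # data generated from the model itself: a single linear rate with
        # subject heterogeneity; the REML fixed effects must land within
        # Monte-Carlo distance of the generating values
        from gestimpute import simulate_cohort, study2_preset
        from dataclasses import replace

        params = replace(
            study2_preset(n_subjects=500, seed=42),
            traj_rate1=0.35,
            traj_rate2=0.35,
            changepoint=13.0,
        )
        ds, _ = simulate_cohort(params)
        fit = fit_mixed(ds, BasisSpec.polynomial(1))
        slope = fit.fe_params[1]
        # MC SE of the slope: slope heterogeneity 0.1 across 500 subjects
        se = 0.1 / np.sqrt(500)
        assert abs(slope - 0.35) < 3 * se


def blup_oracle(ds, fit, subject_id, t):
    """Closed-form conditional-normal BLUP, coded independently of the fit
    path: E[effects | y_i] = Psi Z_i' V_i^{-1} (y_i - X_i beta), with
    V_i = Z_i Psi Z_i' + sigma^2 I, at the fitted variance components."""
    series = ds.subject_series(subject_id)
    t_i = series["gest_week"].to_numpy()
    y_i = series["weight"].to_numpy()
    Z = np.column_stack([np.ones(len(t_i)), t_i])
    X = Z  # linear basis, no covariates
    psi, sigma2 = fit.cov_re, fit.scale
    V = Z @ psi @ Z.T + sigma2 * np.eye(len(t_i))
    dev = psi @ Z.T @ np.linalg.solve(V, y_i - X @ fit.fe_params)
    z_t = np.array([1.0, t])
    return float(z_t @ fit.fe_params + z_t @ dev)


class TestBLUPOracle:
    def test_impute_mixed_matches_conditional_normal_mean(self):
        rng = np.random.default_rng(99)
        rows = []
        for i in range(5):
            a, b = 55 + rng.normal(0, 4), 0.4 + rng.normal(0, 0.08)
            for t in (10.0, 17.0, 24.0, 31.0):
                rows.append((f"T{i}", t, a + b * t + rng.normal(0, 1.2)))
        ds = make_dataset(rows)
        fit = fit_mixed(ds, BasisSpec.polynomial(1))
        for sid in ds.subject_ids:
            r = ImputationRequest.from_dataset(ds, sid, 14.0)
            assert impute_mixed(fit, r) == pytest.approx(
                blup_oracle(ds, fit, sid, 14.0), abs=1e-6
            )


class TestGEE:
    def test_residual_identity(self, common_slope_cohort):
        ds, _ = common_slope_cohort
        fit = fit_gee(ds, BasisSpec.polynomial(1), working="exchangeable")
        df = ds.to_frame()
        X = np.column_stack([np.ones(len(df)), df["gest_week"]])
        recomputed = df["weight"].to_numpy() - X @ fit.params
        stored = fit.residuals.sort_values(["subject_id", "gest_week"])["resid"].to_numpy()
        assert np.max(np.abs(stored - recomputed)) < 1e-10

    def test_independence_equals_pooled_ols(self):
        rng = np.random.default_rng(21)
        rows = []
        for i in range(12):
            for t in np.sort(rng.uniform(6, 40, 5)):
                rows.append((f"G{i}", float(t), float(50 + 0.4 * t + rng.normal(0, 2))))
        ds = make_dataset(rows)
        fit = fit_gee(ds, BasisSpec.polynomial(2), working="independence")
        df = ds.to_frame()
        X = np.column_stack([np.ones(len(df)), df["gest_week"], df["gest_week"] ** 2])
        beta_ols, *_ = np.linalg.lstsq(X, df["weight"].to_numpy(), rcond=None)
        assert fit.params == pytest.approx(beta_ols, abs=1e-8)

    def test_constant_offset_construction_residuals_and_exactness(
        self, common_slope_cohort
    ):
        ds, slope = common_slope_cohort
        fit = fit_gee(ds, BasisSpec.polynomial(1), working="exchangeable")
        # identical visit grids => the pooled slope is the common slope and
        # every residual of a subject equals that subject's vertical offset
        for sid in ds.subject_ids:
            res = fit.subject_residuals(sid)["resid"].to_numpy()
            assert np.allclose(res, res[0], atol=1e-8)
            r = ImputationRequest.from_dataset(ds, sid, 14.0)
            truth = ds.subject_series(sid)["weight"].iloc[0] - slope * 10.0 + slope * 14.0
            for mode in ("mean_residual", "nearest_residual"):
                assert impute_gee(fit, r, mode=mode) == pytest.approx(truth, abs=1e-6)

    def test_unknown_subject_raises(self, common_slope_cohort):
        ds, _ = common_slope_cohort
        fit = fit_gee(ds, BasisSpec.polynomial(1), working="exchangeable")
        with pytest.raises(UnknownSubjectError):
            impute_gee(fit, req([], 14.0, sid="GHOST"))


class TestGEEOffsetArithmetic:
    def make_fit(self, resid_rows):
        return GEEFit(
            spec=BasisSpec.polynomial(1),
            knots=None,
            params=np.array([41.0, 1.0]),  # marginal prediction at t=14 is 55
            fe_names=["intercept", "g1"],
            residuals=pd.DataFrame(resid_rows, columns=["subject_id", "gest_week", "resid"]),
            working="exchangeable",
            requested_working="exchangeable",
            covariate_names=[],
            subject_covariate_rows=None,
        )

    def test_mean_residual_offset(self):
        fit = self.make_fit([("A", 12.0, 1.0), ("A", 30.0, 3.0)])
        assert impute_gee(fit, req([], 14.0, sid="A"), "mean_residual") == pytest.approx(57.0)

    def test_nearest_residual_offset(self):
        fit = self.make_fit([("A", 12.0, 1.0), ("A", 30.0, 3.0)])
        assert impute_gee(fit, req([], 14.0, sid="A"), "nearest_residual") == pytest.approx(56.0)

    def test_nearest_residual_tie_breaks_earlier(self):
        fit = self.make_fit([("A", 13.0, 1.0), ("A", 15.0, 3.0)])
        assert impute_gee(fit, req([], 14.0, sid="A"), "nearest_residual") == pytest.approx(56.0)


class TestLogScalePipeline:
    def test_log_imputation_back_transforms_to_exp(self, common_slope_cohort):
        ds, _ = common_slope_cohort
        logged = transform_log(ds)
        r_nat = ImputationRequest.from_dataset(logged, "C1", 14.0)
        log_value = impute_nearest(r_nat)
        assert back_transform(log_value) == pytest.approx(np.exp(log_value))


class TestCovariates:
    def test_covariates_enter_as_fixed_effects(self):
        rng = np.random.default_rng(5)
        rows, ages = [], {}
        for i in range(20):
            sid = f"V{i}"
            ages[sid] = float(rng.uniform(18, 40))
            a, b = 50 + 0.2 * ages[sid] + rng.normal(0, 1), 0.4
            for t in np.linspace(8, 32, 5):
                rows.append((sid, float(t), a + b * t + rng.normal(0, 0.8)))
        cov = pd.DataFrame(
            {"age_years": [ages[f"V{i}"] for i in range(20)]},
            index=pd.Index([f"V{i}" for i in range(20)], name="subject_id"),
        )
        ds = make_dataset(rows, covariates=cov)
        fit = fit_mixed(ds, BasisSpec.polynomial(1), covariates=["age_years"])
        assert "age_years" in fit.fe_names
        age_coef = fit.fe_params[fit.fe_names.index("age_years")]
        assert age_coef == pytest.approx(0.2, abs=0.15)
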