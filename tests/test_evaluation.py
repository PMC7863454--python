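import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gestimpute import (
    MethodSpec,
    BasisSpec,
    SplitSpec,
    VariantSpec,
    build_split,
    compute_metrics,
    default_grid,
    run_grid,
    simulate_cohort,
    study2_preset,
)
from gestimpute.errors import InfeasibleSplitError, NoDataError, ParameterError

from conftest import make_dataset


def eligible_cohort(n=12, in_window_week=14.0):
    rows = []
    for i in range(n):
        rows += [
            (f"E{i}", 10.0, 55.0 + i),
            (f"E{i}", in_window_week, 56.5 + i),
            (f"E{i}", 20.0, 59.0 + i),
        ]
    return make_dataset(rows)


class TestSplit:
    def test_subject_without_enough_measures_is_ineligible(self):
        ds = make_dataset([("A", 14.0, 60.0)] + [(f"E{i}", w, 55.0 + w) for i in range(3) for w in (10.0, 14.0, 20.0)])
        train, targets = build_split(ds, SplitSpec(n_test=3, seed=0))
        assert "A" not in {t.subject_id for t in targets}

    def test_in_window_measure_required(self):
        ds = make_dataset(
            [("B", 20.0, 60.0), ("B", 24.0, 62.0)]
            + [(f"E{i}", w, 55.0 + w) for i in range(2) for w in (10.0, 14.0, 20.0)]
        )
        with pytest.raises(InfeasibleSplitError) as exc:
            build_split(ds, SplitSpec(n_test=3, seed=0))
        assert exc.value.eligible == 2

    def test_target_is_closest_to_anchor(self):
        ds = make_dataset(
            [("S", 13.2, 58.0), ("S", 14.5, 59.0), ("S", 30.0, 66.0)]
        )
        train, targets = build_split(ds, SplitSpec(n_test=1, seed=0))
        assert targets[0].target_week == 14.5  # |14.5-14| = 0.5 < 0.8

    def test_anchor_tie_breaks_earlier(self):
        ds = make_dataset([("S", 13.5, 58.0), ("S", 14.5, 59.0), ("S", 30.0, 66.0)])
        _, targets = build_split(ds, SplitSpec(n_test=1, seed=0))
        assert targets[0].target_week == 13.5

    def test_conservation_and_no_leakage(self):
        ds, _ = simulate_cohort(study2_preset(n_subjects=150, seed=5))
        spec = SplitSpec(n_test=40, seed=9)
        train, targets = build_split(ds, spec)
        assert train.n_measurements + len(targets) == ds.n_measurements
        tf = train.to_frame()
        for t in targets:
            hit = (tf["subject_id"] == t.subject_id) & (tf["gest_week"] == t.target_week)
            assert not hit.any()
        # non-target measurements of test subjects remain in training
        for t in targets:
            assert (tf["subject_id"] == t.subject_id).any()

    def test_seeded_reproducibility(self):
        ds, _ = simulate_cohort(study2_preset(n_subjects=120, seed=2))
        a = build_split(ds, SplitSpec(n_test=30, seed=4))
        b = build_split(ds, SplitSpec(n_test=30, seed=4))
        assert [t.subject_id for t in a[1]] == [t.subject_id for t in b[1]]
        pd.testing.assert_frame_equal(a[0].to_frame(), b[0].to_frame())

    def test_infeasible_split_reports_eligible_count(self):
        ds = eligible_cohort(n=5)
        with pytest.raises(InfeasibleSplitError) as exc:
            build_split(ds, SplitSpec(n_test=6, seed=0))
        assert exc.value.eligible == 5

    def test_spec_validation(self):
        with pytest.raises(ParameterError):
            SplitSpec(n_test=0)
        with pytest.raises(ParameterError):
            SplitSpec(window=(15.0, 16.0))  # anchor outside window


class TestMetrics:
    def test_hand_computed_example(self):
        rec = compute_metrics([(60.0, 59.0), (62.0, 64.0)])
        assert rec.mae == pytest.approx(1.5)
        assert rec.mse == pytest.approx(2.5)
        assert rec.pct_within_2kg == 1.0

    def test_perfect_imputation(self):
        rec = compute_metrics([(60.0, 60.0), (70.0, 70.0), (55.0, 55.0)])
        assert rec.mae == 0.0
        assert rec.mse == 0.0
        assert rec.spearman_r == pytest.approx(1.0)
        assert rec.pct_within_2kg == 1.0

    def test_within_2kg_boundary_inclusive(self):
        rec = compute_metrics([(60.5, 60.0), (62.0, 60.0), (63.1, 60.0)])
        assert rec.pct_within_2kg == pytest.approx(2 / 3)

    def test_constant_vector_correlation_missing(self):
        rec = compute_metrics([(60.0, 59.0), (60.0, 64.0)])
        assert rec.spearman_r is None

    def test_empty_pairs(self):
        with pytest.raises(NoDataError):
            compute_metrics([])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(30, 120, allow_nan=False), st.floats(30, 120, allow_nan=False)
            ),
            min_size=1,
            max_size=40,
        )
    )
    def test_naive_loop_oracle(self, pairs):
        rec = compute_metrics(pairs)
        abs_err = [abs(i - o) for i, o in pairs]
        sq_err = [(i - o) ** 2 for i, o in pairs]
        within = [1.0 if e <= 2.0 else 0.0 for e in abs_err]
        assert rec.mae == pytest.approx(sum(abs_err) / len(pairs), abs=1e-12)
        assert rec.mse == pytest.approx(sum(sq_err) / len(pairs), abs=1e-12)
        assert rec.pct_within_2kg == pytest.approx(sum(within) / len(pairs), abs=1e-12)


class TestGrid:
    def test_single_nearest_cell(self):
        ds = eligible_cohort()
        report = run_grid(ds, SplitSpec(n_test=5, seed=1), [MethodSpec("nearest")])
        assert len(report.cells) == 1
        cell = report.cells[0]
        assert cell.status == "ok"
        assert cell.metrics.n_evaluated + cell.metrics.n_failed == report.n_targets

    def test_determinism(self):
        ds, _ = simulate_cohort(study2_preset(n_subjects=120, seed=8))
        kwargs = dict(split=SplitSpec(n_test=30, seed=3), grid=default_grid())
        a = run_grid(ds, **kwargs)
        b = run_grid(ds, **kwargs)
        assert a.to_dataframe().to_csv() == b.to_dataframe().to_csv()
        assert a.to_text() == b.to_text()

    def test_log_scale_metrics_stay_in_kg(self):
        ds = eligible_cohort()
        plain = run_grid(ds, SplitSpec(n_test=5, seed=1), [MethodSpec("nearest")])
        logged = run_grid(
            ds,
            SplitSpec(n_test=5, seed=1),
            [MethodSpec("nearest")],
            VariantSpec(log_scale=True),
        )
        # nearest on the log scale back-transforms to the same observed kg
        assert logged.cells[0].metrics.mae == pytest.approx(
            plain.cells[0].metrics.mae, abs=1e-9
        )
        assert logged.cells[0].metrics.mae < 10  # kg, not log units

    def test_failing_cell_does_not_abort_grid(self):
        # 3 distinct visit weeks cannot support 5 spline knots
        ds = eligible_cohort()
        report = run_grid(
            ds,
            SplitSpec(n_test=5, seed=1),
            [MethodSpec("mixed", basis=BasisSpec.rcs(5)), MethodSpec("nearest")],
        )
        assert report.cells[0].status == "failed"
        assert report.cells[1].status == "ok"
        assert "N/A" in report.to_text()

    def test_variants_leave_targets_untouched(self):
        ds, _ = simulate_cohort(study2_preset(n_subjects=120, seed=8))
        spec = SplitSpec(n_test=30, seed=3)
        plain = run_grid(ds, spec, [MethodSpec("nearest")])
        varied = run_grid(
            ds, spec, [MethodSpec("nearest")], VariantSpec(drop_t3=True, log_scale=True)
        )
        obs_plain = {(r[0], r[2]) for r in plain.cells[0].predictions}
        obs_varied = {(r[0], r[2]) for r in varied.cells[0].predictions}
        assert {o for _, o in obs_plain} == {o for _, o in obs_varied}

    def test_empty_grid_rejected(self):
        with pytest.raises(ParameterError):
            run_grid(eligible_cohort(), SplitSpec(n_test=5, seed=1), [])

    def test_full_comparison_grid_composition(self):
        from gestimpute import table2_grid

        grid = table2_grid()
        labels = [m.label for m in grid]
        assert len(labels) == len(set(labels)) == 29
        assert sum(1 for m in grid if m.method == "mixed") == 9
        assert sum(1 for m in grid if m.method == "gee") == 18
        assert {m.gee_mode for m in grid if m.method == "gee"} == {
            "mean_residual",
            "nearest_residual",
        }
        kinds = {(m.basis.kind, m.basis.n_knots or m.basis.degree) for m in grid if m.basis}
        assert kinds == {("rcs", 3), ("rcs", 4), ("rcs", 5), ("polynomial", 1), ("polynomial", 2), ("polynomial", 3)}
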