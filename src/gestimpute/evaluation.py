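"""Train/test protocol, accuracy metrics and the method-comparison grid.

The protocol withholds, for each of ``n_test`` randomly sampled eligible
subjects, the single measurement in the 13-15-week window closest to 14
weeks 0 days; that withheld weight is the ground truth. All other
measurements — including the test subjects' remaining visits — stay in the
training set. Eligibility requires at least one in-window measurement and at
least ``min_measures`` measurements overall.

Accuracy is summarized per method as mean absolute error (MAE, kg; with SD
and IQR of the absolute errors), mean squared error (MSE, kg^2), Spearman
rank correlation of imputed vs observed, and the proportion of subjects
imputed within 2 kg (inclusive). ``run_grid`` evaluates a list of method
configurations on one shared split, applying any sensitivity variants
(drop third-trimester weights, add covariates, log-transform) to the
training data only; model convergence failures are recorded as "N/A" cells
rather than aborting the grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    WeightDataset,
    back_transform,
    drop_third_trimester,
    transform_log,
)
from .errors import (
    ConvergenceFailure,
    DegenerateKnotsError,
    InfeasibleSplitError,
    NoDataError,
    ParameterError,
    UnknownSubjectError,
)
from .imputers import (
    ImputationRequest,
    fit_gee,
    fit_mixed,
    impute_gee,
    impute_mixed,
    impute_nearest,
    impute_two_point,
)
from .time_basis import BasisSpec

__all__ = [
    "SplitSpec",
    "TestTarget",
    "MethodSpec",
    "VariantSpec",
    "MetricRecord",
    "CellResult",
    "EvaluationReport",
    "build_split",
    "compute_metrics",
    "run_grid",
    "default_grid",
    "table2_grid",
]


@dataclass(frozen=True)
class SplitSpec:
    """Testing-set construction parameters.

    ``window`` is the eligibility window in gestational weeks, ``anchor``
    the target definition (closest measurement wins), ``n_test`` the number
    of subjects sampled without replacement, ``min_measures`` the minimum
    total measurements per eligible subject.
    """

    window: tuple[float, float] = (13.0, 15.0)
    anchor: float = 14.0
    n_test: int = 200
    min_measures: int = 2
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.window
        if not lo < self.anchor < hi:
            raise ParameterError("window must bracket the anchor week")
        if self.n_test < 1:
            raise ParameterError("n_test must be >= 1")
        if self.min_measures < 2:
            raise ParameterError("min_measures must be >= 2")

    def to_dict(self) -> dict:
        return {
            "window": list(self.window),
            "anchor": self.anchor,
            "n_test": self.n_test,
            "min_measures": self.min_measures,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class TestTarget:
    """One withheld measurement: the ground truth for one test subject."""

    subject_id: str
    target_week: float
    observed_weight: float


def build_split(
    ds: WeightDataset, spec: SplitSpec
) -> tuple[WeightDataset, list[TestTarget]]:
    """Draw the testing sample and withhold one target measurement each.

    Subjects are eligible when they have >= 1 measurement inside the window
    and >= ``min_measures`` measurements overall; ``n_test`` of them are
    drawn by seeded simple random sampling. Per test subject the in-window
    measurement closest to the anchor (ties toward the earlier week) becomes
    the :class:`TestTarget` and is removed from the returned training copy.
    Raises :class:`InfeasibleSplitError` (reporting the eligible count) when
    too few subjects qualify.
    """
    df = ds.to_frame()
    lo, hi = spec.window
    in_window = (df["gest_week"] >= lo) & (df["gest_week"] <= hi)
    counts = df.groupby("subject_id").size()
    has_window = df.loc[in_window].groupby("subject_id").size()
    eligible = sorted(
        set(counts.index[counts >= spec.min_measures]) & set(has_window.index)
    )
    if len(eligible) < spec.n_test:
        raise InfeasibleSplitError(eligible=len(eligible), requested=spec.n_test)

    rng = np.random.default_rng(spec.seed)
    chosen = rng.choice(np.array(eligible, dtype=object), size=spec.n_test, replace=False)

    targets: list[TestTarget] = []
    drop_index: list[int] = []
    for sid in sorted(chosen):
        rows = df.loc[(df["subject_id"] == sid) & in_window]
        dist = (rows["gest_week"] - spec.anchor).abs()
        order = np.lexsort((rows["gest_week"].to_numpy(), dist.to_numpy()))
        pick = rows.iloc[order[0]]
        targets.append(
            TestTarget(
                subject_id=str(sid),
                target_week=float(pick["gest_week"]),
                observed_weight=float(pick["weight"]),
            )
        )
        drop_index.append(pick.name)

    train = ds._replace_frame(df.drop(index=drop_index))
    return train, targets


# ----------------------------------------------------------------- metrics


@dataclass(frozen=True)
class MetricRecord:
    """Imputation-accuracy summary over a testing set (one grid cell)."""

    mae: float
    mae_sd: float
    mae_iqr: tuple[float, float]
    mse: float
    spearman_r: Optional[float]
    pct_within_2kg: float
    n_evaluated: int
    n_failed: int = 0

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "mae_sd": self.mae_sd,
            "mae_iqr_low": self.mae_iqr[0],
            "mae_iqr_high": self.mae_iqr[1],
            "mse": self.mse,
            "spearman_r": self.spearman_r,
            "pct_within_2kg": self.pct_within_2kg,
            "n_evaluated": self.n_evaluated,
            "n_failed": self.n_failed,
        }


def compute_metrics(
    pairs: Sequence[tuple[float, float]], n_failed: int = 0
) -> MetricRecord:
    """Accuracy metrics from (imputed, observed) pairs, both in kg.

    MAE is the mean absolute difference; its SD and IQR are over the absolute
    differences. MSE is in kg^2. Spearman correlation uses average ranks for
    ties and is reported as missing (None) when either vector is constant.
    "Within 2 kg" is inclusive of the boundary.
    """
    if len(pairs) == 0:
        raise NoDataError("no (imputed, observed) pairs to score")
    arr = np.asarray(pairs, dtype=float)
    imputed, observed = arr[:, 0], arr[:, 1]
    diffs = np.abs(imputed - observed)
    q1, q3 = np.percentile(diffs, [25, 75])
    if len(arr) >= 2 and np.ptp(imputed) > 0 and np.ptp(observed) > 0:
        rho = float(stats.spearmanr(imputed, observed).statistic)
    else:
        rho = None
    return MetricRecord(
        mae=float(diffs.mean()),
        mae_sd=float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0,
        mae_iqr=(float(q1), float(q3)),
        mse=float(((imputed - observed) ** 2).mean()),
        spearman_r=rho,
        pct_within_2kg=float((diffs <= 2.0).mean()),
        n_evaluated=len(arr),
        n_failed=int(n_failed),
    )


# -------------------------------------------------------------------- grid


@dataclass(frozen=True)
class MethodSpec:
    """One grid cell: an imputation method plus its options."""

    method: str  # nearest | two_point | mixed | gee
    basis: Optional[BasisSpec] = None
    gee_mode: str = "mean_residual"
    working: str = "unstructured"
    random_structure: str = "full"

    def __post_init__(self):
        if self.method not in ("nearest", "two_point", "mixed", "gee"):
            raise ParameterError(f"unknown method {self.method!r}")
        if self.method in ("mixed", "gee") and self.basis is None:
            raise ParameterError(f"method {self.method!r} requires a basis")

    @property
    def label(self) -> str:
        if self.method == "nearest":
            return "nearest"
        if self.method == "two_point":
            return "two_point"
        if self.method == "mixed":
            return f"mixed[{self.basis.label}]"
        mode = "mean" if self.gee_mode == "mean_residual" else "nearest"
        return f"gee[{self.basis.label},{mode}]"

    def to_dict(self) -> dict:
        d: dict = {"method": self.method}
        if self.basis is not None:
            d["basis"] = self.basis.to_dict()
        if self.method == "gee":
            d["gee_mode"] = self.gee_mode
            d["working"] = self.working
        if self.method == "mixed" and self.random_structure != "full":
            d["random_structure"] = self.random_structure
        return d

    @staticmethod
    def from_dict(d: dict) -> "MethodSpec":
        known = {"method", "basis", "gee_mode", "working", "random_structure"}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown method keys: {sorted(unknown)}")
        basis = d.get("basis")
        return MethodSpec(
            method=d["method"],
            basis=None if basis is None else BasisSpec.from_dict(basis),
            gee_mode=d.get("gee_mode", "mean_residual"),
            working=d.get("working", "unstructured"),
            random_structure=d.get("random_structure", "full"),
        )


@dataclass(frozen=True)
class VariantSpec:
    """Sensitivity-analysis switches, applied to the training data only.

    Composition order is fixed: drop third-trimester weights, then
    log-transform, then fit; covariates enter the model fits directly.
    Test targets' observed weights always stay on the natural kg scale.
    """

    drop_t3: bool = False
    t3_cutoff: float = 28.0
    covariates: tuple[str, ...] = ()
    log_scale: bool = False

    def to_dict(self) -> dict:
        return {
            "drop_t3": self.drop_t3,
            "t3_cutoff": self.t3_cutoff,
            "covariates": list(self.covariates),
            "log_scale": self.log_scale,
        }


@dataclass
class CellResult:
    """Outcome of one grid cell: metrics, or an N/A with its reason."""

    spec: MethodSpec
    status: str  # "ok" | "failed"
    metrics: Optional[MetricRecord] = None
    reason: Optional[str] = None
    predictions: list[tuple[str, float, float, float]] = field(default_factory=list)
    # predictions rows: (subject_id, target_week, observed_kg, imputed_kg)


@dataclass
class EvaluationReport:
    """All grid cells plus split bookkeeping; renders CSV/text artifacts."""

    cells: list[CellResult]
    split: SplitSpec
    variants: VariantSpec
    n_train_measurements: int
    n_targets: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for cell in self.cells:
            row = {"method": cell.spec.label, "status": cell.status}
            if cell.metrics is not None:
                row.update(cell.metrics.to_dict())
            else:
                row["reason"] = cell.reason
            rows.append(row)
        return pd.DataFrame(rows)

    def predictions_frame(self) -> pd.DataFrame:
        rows = []
        for cell in self.cells:
            for sid, tw, obs, imp in cell.predictions:
                rows.append(
                    {
                        "method": cell.spec.label,
                        "subject_id": sid,
                        "target_week": tw,
                        "observed": obs,
                        "imputed": imp,
                    }
                )
        return pd.DataFrame(
            rows, columns=["method", "subject_id", "target_week", "observed", "imputed"]
        )

    def to_text(self) -> str:
        """Formatted comparison table (one row per method configuration)."""
        header = (
            f"{'Imputation method':<34} {'MAE (kg)':>9} {'MSE':>8} "
            f"{'r':>6} {'<=2kg':>7} {'n':>5}"
        )
        lines = [header, "-" * len(header)]
        for cell in self.cells:
            if cell.metrics is None:
                lines.append(f"{cell.spec.label:<34} {'N/A':>9}  ({cell.reason})")
                continue
            m = cell.metrics
            rho = f"{m.spearman_r:.2f}" if m.spearman_r is not None else "--"
            lines.append(
                f"{cell.spec.label:<34} {m.mae:>9.2f} {m.mse:>8.2f} "
                f"{rho:>6} {m.pct_within_2kg:>6.0%} {m.n_evaluated:>5d}"
            )
        return "\n".join(lines) + "\n"

    def cell(self, label: str) -> CellResult:
        for c in self.cells:
            if c.spec.label == label:
                return c
        raise KeyError(label)


def default_grid() -> list[MethodSpec]:
    """The four methods, model-based ones with a linear time term."""
    lin = BasisSpec.polynomial(1)
    return [
        MethodSpec("nearest"),
        MethodSpec("two_point"),
        MethodSpec("mixed", basis=lin),
        MethodSpec("gee", basis=lin, gee_mode="mean_residual"),
    ]


def table2_grid(working: str = "unstructured") -> list[MethodSpec]:
    """The full comparison grid: every basis for the mixed model, every
    basis x residual mode for GEE, plus the two simple methods."""
    from .time_basis import FIXED_PERCENTILES

    bases = [
        BasisSpec.rcs(3),
        BasisSpec.rcs(4),
        BasisSpec.rcs(5),
        BasisSpec.rcs(3, "fixed_percentiles", FIXED_PERCENTILES[3]),
        BasisSpec.rcs(4, "fixed_percentiles", FIXED_PERCENTILES[4]),
        BasisSpec.rcs(5, "fixed_percentiles", FIXED_PERCENTILES[5]),
        BasisSpec.polynomial(1),
        BasisSpec.polynomial(2),
        BasisSpec.polynomial(3),
    ]
    grid = [MethodSpec("mixed", basis=b) for b in bases]
    for mode in ("mean_residual", "nearest_residual"):
        grid += [
            MethodSpec("gee", basis=b, gee_mode=mode, working=working) for b in bases
        ]
    grid += [MethodSpec("nearest"), MethodSpec("two_point")]
    return grid


def _apply_variants(train: WeightDataset, variants: VariantSpec) -> WeightDataset:
    out = train
    if variants.drop_t3:
        out = drop_third_trimester(out, cutoff_week=variants.t3_cutoff)
    if variants.log_scale:
        out = transform_log(out)
    return out


def _run_cell(
    cell_spec: MethodSpec,
    train: WeightDataset,
    targets: Sequence[TestTarget],
    variants: VariantSpec,
) -> CellResult:
    log_scale = variants.log_scale
    covariates = list(variants.covariates) or None

    fit = None
    if cell_spec.method in ("mixed", "gee"):
        try:
            if cell_spec.method == "mixed":
                fit = fit_mixed(
                    train,
                    cell_spec.basis,
                    covariates=covariates,
                    random_structure=cell_spec.random_structure,
                )
            else:
                fit = fit_gee(
                    train,
                    cell_spec.basis,
                    working=cell_spec.working,
                    covariates=covariates,
                )
        except (ConvergenceFailure, DegenerateKnotsError) as exc:
            return CellResult(spec=cell_spec, status="failed", reason=str(exc))

    pairs: list[tuple[float, float]] = []
    predictions: list[tuple[str, float, float, float]] = []
    n_failed = 0
    for tgt in targets:
        req = ImputationRequest.from_dataset(train, tgt.subject_id, tgt.target_week)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if cell_spec.method == "nearest":
                    value = impute_nearest(req)
                elif cell_spec.method == "two_point":
                    value = impute_two_point(req)
                elif cell_spec.method == "mixed":
                    value = impute_mixed(fit, req)
                else:
                    value = impute_gee(fit, req, mode=cell_spec.gee_mode)
        except (NoDataError, UnknownSubjectError):
            n_failed += 1
            continue
        if log_scale:
            value = back_transform(value)
        pairs.append((value, tgt.observed_weight))
        predictions.append((tgt.subject_id, tgt.target_week, tgt.observed_weight, value))

    if not pairs:
        return CellResult(
            spec=cell_spec, status="failed", reason="no target could be imputed"
        )
    return CellResult(
        spec=cell_spec,
        status="ok",
        metrics=compute_metrics(pairs, n_failed=n_failed),
        predictions=predictions,
    )


def run_grid(
    ds: WeightDataset,
    split: SplitSpec,
    grid: Sequence[MethodSpec],
    variants: Optional[VariantSpec] = None,
) -> EvaluationReport:
    """Evaluate every method configuration on one shared train/test split.

    The split is built once; sensitivity variants transform the training
    data only (targets stay observed, in kg). Individual cell failures —
    chiefly mixed-model convergence on flexible bases — never abort the
    grid; they appear as "N/A" cells with the failure reason.
    """
    if not grid:
        raise ParameterError("grid must contain at least one method")
    variants = variants or VariantSpec()
    train, targets = build_split(ds, split)
    train_v = _apply_variants(train, variants)
    cells = [_run_cell(spec, train_v, targets, variants) for spec in grid]
    return EvaluationReport(
        cells=cells,
        split=split,
        variants=variants,
        n_train_measurements=train.n_measurements,
        n_targets=len(targets),
    )
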