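"""The four early-pregnancy weight imputation methods.

Given a subject's repeated weight measurements W_ij at gestational weeks
t_ij, each method produces a subject-specific weight at a target week t
(typically 14.0, the end of the first trimester):

1. **Nearest measure** — the training weight measured closest in time to t.
2. **Two-point arithmetic** — the line through the two training measurements
   closest to t, evaluated at t (interpolation or extrapolation).
3. **Mixed-effects model** — W_ij = b_i + beta_i' g(t_ij) + eps_ij with
   correlated subject-specific random intercept and slopes on every column
   of g (unstructured covariance, REML). The imputation is the subject's
   empirical-Bayes (BLUP) curve b_hat_i + beta_hat_i' g(t), where the hats
   denote fixed effects plus BLUP deviations.
4. **GEE marginal model** — W_ij = gamma + alpha' g(t_ij) + e_ij estimated by
   generalized estimating equations; the population prediction
   gamma_hat + alpha_hat' g(t) is individualized by adding a subject
   residual offset: the subject's mean training residual (``mean_residual``)
   or the residual at the training time closest to t (``nearest_residual``).

Ties in any "closest" rule break toward the earlier gestational week.
Model fitting is delegated to statsmodels (MixedLM, GEE); this module owns
the basis handling, the subject-specific prediction rules and the residual
bookkeeping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.genmod.cov_struct import Exchangeable, Independence, Unstructured
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .data_model import WeightDataset
from .errors import (
    ConvergenceFailure,
    NoDataError,
    ParameterError,
    PopulationOnlyWarning,
    UnknownSubjectError,
)
from .time_basis import BasisSpec, KnotVector, design_matrix, design_row, knots_from_percentiles

__all__ = [
    "ImputationRequest",
    "MixedModelFit",
    "GEEFit",
    "impute_nearest",
    "impute_two_point",
    "fit_mixed",
    "impute_mixed",
    "fit_gee",
    "impute_gee",
]


@dataclass(frozen=True)
class ImputationRequest:
    """A subject, a target gestational week, and the training series.

    The observed weight at the target week must never appear in ``series``;
    the evaluation split enforces this upstream.
    """

    subject_id: str
    target_week: float
    series: pd.DataFrame  # columns: gest_week, weight

    @staticmethod
    def from_dataset(
        ds: WeightDataset, subject_id: str, target_week: float
    ) -> "ImputationRequest":
        return ImputationRequest(
            subject_id=str(subject_id),
            target_week=float(target_week),
            series=ds.subject_series(subject_id),
        )


def _nearest_order(series: pd.DataFrame, target: float) -> pd.DataFrame:
    """Rows sorted by |t - target|, ties toward the earlier week."""
    s = series.sort_values("gest_week", kind="mergesort")
    dist = (s["gest_week"] - target).abs()
    return s.iloc[np.lexsort((s["gest_week"].to_numpy(), dist.to_numpy()))]


# -------------------------------------------------------- simple imputers


def impute_nearest(req: ImputationRequest) -> float:
    """Weight of the training measurement closest in time to the target."""
    if len(req.series) == 0:
        raise NoDataError(f"subject {req.subject_id} has no training measurements")
    return float(_nearest_order(req.series, req.target_week)["weight"].iloc[0])


def impute_two_point(req: ImputationRequest) -> float:
    """Linear rate between the two measurements closest to the target.

    With (t1, w1), (t2, w2) the two nearest measurements, returns
    w1 + (w2 - w1)/(t2 - t1) * (target - t1) — valid both for interior
    interpolation and for extrapolation beyond the observed span.
    """
    if len(req.series) < 2:
        raise NoDataError(
            f"subject {req.subject_id} has fewer than 2 training measurements"
        )
    two = _nearest_order(req.series, req.target_week).iloc[:2]
    (t1, w1), (t2, w2) = two[["gest_week", "weight"]].to_numpy()
    if t1 == t2:
        warnings.warn(
            f"tied measurement times for subject {req.subject_id}; "
            "falling back to nearest-measure imputation",
            stacklevel=2,
        )
        return impute_nearest(req)
    return float(w1 + (w2 - w1) / (t2 - t1) * (req.target_week - t1))


# ------------------------------------------------------- design utilities


def _covariate_design(
    train: WeightDataset, covariates: Sequence[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Per-subject covariate design rows (numeric passthrough, dummy-coded
    categories with the first level as reference)."""
    cov = train.covariates_frame()
    if cov is None:
        raise ParameterError("dataset carries no covariates")
    missing = [c for c in covariates if c not in cov.columns]
    if missing:
        raise ParameterError(f"covariates not in dataset: {missing}")
    sub = cov.loc[:, list(covariates)]
    if sub.isna().any().any():
        raise ParameterError("missing covariate values; complete cases required")
    parts = []
    for c in covariates:
        col = sub[c]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(col.astype(float).to_frame(c))
        else:
            parts.append(pd.get_dummies(col.astype(str), prefix=c, drop_first=True).astype(float))
    design = pd.concat(parts, axis=1)
    return design, list(design.columns)


def _model_matrices(
    train: WeightDataset,
    spec: BasisSpec,
    covariates: Optional[Sequence[str]],
):
    df = train.to_frame()
    knots = (
        knots_from_percentiles(df["gest_week"].to_numpy(), spec)
        if spec.kind == "rcs"
        else None
    )
    G = design_matrix(df["gest_week"].to_numpy(), spec, knots)
    base_names = ["intercept"] + [f"g{j + 1}" for j in range(G.shape[1])]
    X = np.column_stack([np.ones(len(df)), G])
    cov_rows = None
    cov_names: list[str] = []
    if covariates:
        design, cov_names = _covariate_design(train, covariates)
        cov_rows = design
        X = np.column_stack(
            [X, design.reindex(df["subject_id"]).to_numpy(dtype=float)]
        )
    return df, knots, X, base_names + cov_names, cov_rows


def _require_fit_data(train: WeightDataset) -> None:
    counts = train.to_frame().groupby("subject_id").size()
    if (counts >= 2).sum() < 2:
        raise ParameterError(
            "model fitting requires at least 2 subjects with >= 2 measurements"
        )


# ------------------------------------------------------------ mixed model


def _blup_deviations(
    df: pd.DataFrame,
    X: np.ndarray,
    Z: np.ndarray,
    fe_params: np.ndarray,
    cov_re: np.ndarray,
    scale: float,
) -> dict[str, np.ndarray]:
    """Empirical-Bayes random-effect deviations for every subject.

    Solves the mixed-model-equations form (Z_i'Z_i + sigma^2 Psi^-1) b_i =
    Z_i' (y_i - X_i beta), algebraically identical to the conditional-normal
    mean Psi Z_i' V_i^-1 (y_i - X_i beta) but numerically stable when the
    residual variance is near zero (the noiseless limit, where the BLUP
    degrades gracefully to per-subject least squares). A singular Psi is
    handled by working in its eigenbasis: zero-variance directions get zero
    deviation.
    """
    evals, Q = np.linalg.eigh((cov_re + cov_re.T) / 2.0)
    evals = np.clip(evals, 0.0, None)
    out: dict[str, np.ndarray] = {}
    if evals.max(initial=0.0) <= 0.0:
        zero = np.zeros(Z.shape[1])
        return {str(sid): zero for sid in df["subject_id"].unique()}
    keep = evals > evals.max() * 1e-12
    Qk, lk = Q[:, keep], evals[keep]
    resid = df["weight"].to_numpy() - X @ fe_params
    for sid, idx in df.groupby("subject_id").indices.items():
        Zi = Z[idx] @ Qk
        A = Zi.T @ Zi + scale * np.diag(1.0 / lk)
        c = np.linalg.solve(A, Zi.T @ resid[idx])
        out[str(sid)] = Qk @ c
    return out


@dataclass
class MixedModelFit:
    """Fitted mixed-effects model with subject-specific BLUP curves.

    ``fe_params`` holds the fixed effects for (intercept, g columns,
    covariate columns); ``random_effects`` maps subject id to the BLUP
    *deviations* on (intercept, random-slope columns). ``subject_effects``
    returns the subject-level totals b_hat_i, beta_hat_i (fixed + deviation),
    the quantities the imputation rule uses.
    """

    spec: BasisSpec
    knots: Optional[KnotVector]
    fe_params: np.ndarray
    fe_names: list[str]
    cov_re: np.ndarray
    scale: float
    random_effects: dict[str, np.ndarray]
    re_structure: str  # "full" or "intercept_slope"
    converged: bool
    reml: bool
    covariate_names: list[str]
    subject_covariate_rows: Optional[pd.DataFrame]
    mean_covariate_row: Optional[np.ndarray]

    @property
    def n_base(self) -> int:
        return 1 + self.spec.n_columns

    def _z_row(self, t: float) -> np.ndarray:
        """Random-effects design row [1, g(t)] (or [1, t] if reduced)."""
        if self.re_structure == "intercept_slope":
            return np.array([1.0, float(t)])
        return np.concatenate([[1.0], design_row(t, self.spec, self.knots)])

    def _x_row(self, t: float, subject_id: Optional[str]) -> np.ndarray:
        row = np.concatenate([[1.0], design_row(t, self.spec, self.knots)])
        if self.covariate_names:
            if (
                subject_id is not None
                and self.subject_covariate_rows is not None
                and subject_id in self.subject_covariate_rows.index
            ):
                crow = self.subject_covariate_rows.loc[subject_id].to_numpy(dtype=float)
            else:
                crow = self.mean_covariate_row
            row = np.concatenate([row, crow])
        return row

    def population_prediction(self, t: float, subject_id: Optional[str] = None) -> float:
        """Fixed-effects (population-mean) weight at gestational week t."""
        return float(self._x_row(t, subject_id) @ self.fe_params)

    def subject_effects(self, subject_id: str) -> np.ndarray:
        """Subject totals (b_hat_i, beta_hat_i) on intercept + g columns."""
        sid = str(subject_id)
        if sid not in self.random_effects:
            raise UnknownSubjectError(f"subject {sid} not in the fitted data")
        dev = self.random_effects[sid]
        base = self.fe_params[: self.n_base].copy()
        if self.re_structure == "intercept_slope":
            base[:2] += dev
        else:
            base += dev
        return base


def fit_mixed(
    train: WeightDataset,
    spec: BasisSpec,
    covariates: Optional[Sequence[str]] = None,
    random_structure: str = "full",
    reml: bool = True,
) -> MixedModelFit:
    """Fit the random-intercept/random-slope mixed model by REML.

    Random effects cover the intercept and every column of g(t) with an
    unstructured covariance (``random_structure="full"``, the default).
    ``random_structure="intercept_slope"`` restricts them to intercept +
    linear slope — an escape hatch for flexible bases where the full
    structure will not converge. Non-convergence raises
    :class:`ConvergenceFailure` carrying the basis spec: an expected,
    reportable outcome for flexible bases on sparse data.
    """
    if random_structure not in ("full", "intercept_slope"):
        raise ParameterError(f"unknown random_structure {random_structure!r}")
    _require_fit_data(train)
    df, knots, X, names, cov_rows = _model_matrices(train, spec, covariates)

    if random_structure == "intercept_slope":
        exog_re = np.column_stack([np.ones(len(df)), df["gest_week"].to_numpy()])
    else:
        exog_re = X[:, : 1 + spec.n_columns]

    # Rescale random-slope columns to unit SD for the optimizer: intercept and
    # slope variances can differ by orders of magnitude (kg^2 vs kg^2/week^2),
    # which stalls gradient methods. BLUPs and covariance are mapped back to
    # the original units below; fitted curves are invariant to the scaling.
    exog_re_raw = exog_re
    re_scale = np.ones(exog_re.shape[1])
    sds = exog_re[:, 1:].std(axis=0)
    re_scale[1:] = np.where(sds > 0, sds, 1.0)
    exog_re = exog_re / re_scale

    model = sm.MixedLM(
        df["weight"].to_numpy(),
        X,
        groups=df["subject_id"].to_numpy(),
        exog_re=exog_re,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            # lbfgs first for speed; Powell is a derivative-free fallback for
            # small samples and near-degenerate (e.g. noiseless) likelihoods
            res = model.fit(reml=reml, maxiter=500, method=["lbfgs", "powell"])
        except (np.linalg.LinAlgError, ValueError, OverflowError) as exc:
            raise ConvergenceFailure(
                f"mixed model failed for basis {spec.label}: {exc}", spec=spec
            ) from exc
    hard_warn = any(issubclass(w.category, ConvergenceWarning) for w in caught)
    params_ok = np.all(np.isfinite(res.fe_params)) and np.all(
        np.isfinite(np.asarray(res.cov_re))
    )
    if not res.converged or not params_ok:
        raise ConvergenceFailure(
            f"mixed model did not converge for basis {spec.label}", spec=spec
        )

    unscale = np.diag(1.0 / re_scale)
    cov_re = unscale @ np.asarray(res.cov_re, dtype=float) @ unscale
    re_dict = _blup_deviations(
        df, X, exog_re_raw, np.asarray(res.fe_params, dtype=float), cov_re,
        float(res.scale),
    )
    return MixedModelFit(
        spec=spec,
        knots=knots,
        fe_params=np.asarray(res.fe_params, dtype=float),
        fe_names=names,
        cov_re=cov_re,
        scale=float(res.scale),
        random_effects=re_dict,
        re_structure=random_structure,
        converged=bool(res.converged) and not hard_warn,
        reml=reml,
        covariate_names=names[1 + spec.n_columns :],
        subject_covariate_rows=cov_rows,
        mean_covariate_row=(
            None if cov_rows is None else cov_rows.to_numpy(dtype=float).mean(axis=0)
        ),
    )


def impute_mixed(fit: MixedModelFit, req: ImputationRequest) -> float:
    """Subject-specific BLUP imputation b_hat_i + beta_hat_i' g(t).

    For a subject absent from the fit, only the population curve is
    available: the fixed-effects prediction is returned with a
    :class:`PopulationOnlyWarning` (a degraded-quality flag, outside the
    withheld-measurement protocol).
    """
    sid = str(req.subject_id)
    t = float(req.target_week)
    pop = fit.population_prediction(t, subject_id=sid)
    if sid not in fit.random_effects:
        warnings.warn(
            f"subject {sid} unknown to the mixed model; returning the "
            "population-level prediction",
            PopulationOnlyWarning,
            stacklevel=2,
        )
        return pop
    return pop + float(fit._z_row(t) @ fit.random_effects[sid])


# --------------------------------------------------------------- GEE model


@dataclass
class GEEFit:
    """Fitted GEE marginal model plus the per-subject residual store.

    ``residuals`` holds one row per training measurement:
    (subject_id, gest_week, resid) with resid = W_ij - (gamma_hat +
    alpha_hat' g(t_ij) [+ covariates]) — recomputable exactly from the fit.
    """

    spec: BasisSpec
    knots: Optional[KnotVector]
    params: np.ndarray
    fe_names: list[str]
    residuals: pd.DataFrame
    working: str  # structure actually used
    requested_working: str
    covariate_names: list[str]
    subject_covariate_rows: Optional[pd.DataFrame]

    def _x_row(self, t: float, subject_id: Optional[str]) -> np.ndarray:
        row = np.concatenate([[1.0], design_row(t, self.spec, self.knots)])
        if self.covariate_names:
            if (
                subject_id is not None
                and self.subject_covariate_rows is not None
                and subject_id in self.subject_covariate_rows.index
            ):
                crow = self.subject_covariate_rows.loc[subject_id].to_numpy(dtype=float)
            else:
                crow = self.subject_covariate_rows.to_numpy(dtype=float).mean(axis=0)
            row = np.concatenate([row, crow])
        return row

    def population_prediction(self, t: float, subject_id: Optional[str] = None) -> float:
        """Marginal (population-mean) weight at gestational week t."""
        return float(self._x_row(t, subject_id) @ self.params)

    def subject_residuals(self, subject_id: str) -> pd.DataFrame:
        sel = self.residuals.loc[self.residuals["subject_id"] == str(subject_id)]
        if len(sel) == 0:
            raise UnknownSubjectError(
                f"subject {subject_id} has no residuals in the fit"
            )
        return sel.reset_index(drop=True)


_COV_STRUCTS = {
    "unstructured": Unstructured,
    "exchangeable": Exchangeable,
    "independence": Independence,
}


def fit_gee(
    train: WeightDataset,
    spec: BasisSpec,
    working: str = "unstructured",
    covariates: Optional[Sequence[str]] = None,
) -> GEEFit:
    """Estimate the marginal model by GEE and store training residuals.

    Occasions for the unstructured working correlation are indexed by the
    within-subject rank of gestational week (visit counts are unbalanced).
    If unstructured estimation fails, the fit falls back to exchangeable
    with a warning; failure after fallback raises
    :class:`ConvergenceFailure`.
    """
    if working not in _COV_STRUCTS:
        raise ParameterError(f"unknown working correlation {working!r}")
    _require_fit_data(train)
    df, knots, X, names, cov_rows = _model_matrices(train, spec, covariates)
    y = df["weight"].to_numpy()
    groups = df["subject_id"].to_numpy()
    occasion = (
        df.groupby("subject_id")["gest_week"].rank(method="first").astype(int) - 1
    ).to_numpy()

    def _attempt(structure: str):
        model = sm.GEE(
            y,
            X,
            groups=groups,
            time=occasion[:, None],
            family=sm.families.Gaussian(),
            cov_struct=_COV_STRUCTS[structure](),
        )
        res = model.fit(maxiter=200)
        if not np.all(np.isfinite(np.asarray(res.params))):
            raise ConvergenceFailure(
                f"GEE produced non-finite estimates for basis {spec.label}", spec=spec
            )
        return res

    used = working
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = _attempt(working)
        except ConvergenceFailure:
            raise
        except Exception as exc:
            if working == "unstructured":
                warnings.simplefilter("default")
                warnings.warn(
                    f"unstructured GEE failed ({exc}); falling back to exchangeable",
                    stacklevel=2,
                )
                used = "exchangeable"
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    try:
                        res = _attempt("exchangeable")
                    except Exception as exc2:  # noqa: BLE001
                        raise ConvergenceFailure(
                            f"GEE failed after exchangeable fallback for basis "
                            f"{spec.label}: {exc2}",
                            spec=spec,
                        ) from exc2
            else:
                raise ConvergenceFailure(
                    f"GEE failed for basis {spec.label}: {exc}", spec=spec
                ) from exc

    params = np.asarray(res.params, dtype=float)
    resid = pd.DataFrame(
        {
            "subject_id": df["subject_id"].to_numpy(),
            "gest_week": df["gest_week"].to_numpy(),
            "resid": y - X @ params,
        }
    )
    return GEEFit(
        spec=spec,
        knots=knots,
        params=params,
        fe_names=names,
        residuals=resid,
        working=used,
        requested_working=working,
        covariate_names=names[1 + spec.n_columns :],
        subject_covariate_rows=cov_rows,
    )


def impute_gee(
    fit: GEEFit, req: ImputationRequest, mode: str = "mean_residual"
) -> float:
    """Marginal prediction plus a subject residual offset.

    ``mean_residual`` adds the average of the subject's training residuals
    across all available gestational weeks; ``nearest_residual`` adds the
    residual of the training measurement closest to the target week (ties
    toward the earlier week).
    """
    if mode not in ("mean_residual", "nearest_residual"):
        raise ParameterError(f"unknown residual mode {mode!r}")
    sid = str(req.subject_id)
    res = fit.subject_residuals(sid)
    marginal = fit.population_prediction(float(req.target_week), subject_id=sid)
    if mode == "mean_residual":
        offset = float(res["resid"].mean())
    else:
        dist = (res["gest_week"] - req.target_week).abs()
        order = np.lexsort((res["gest_week"].to_numpy(), dist.to_numpy()))
        offset = float(res["resid"].iloc[order[0]])
    return marginal + offset
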