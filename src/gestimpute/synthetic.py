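"""Synthetic pregnancy-weight cohorts with known ground truth.

The generator emulates the longitudinal structure the imputation methods
assume: women enroll at a study-specific gestational age, are weighed at
enrollment and at roughly monthly follow-up visits until delivery, and
individual weight trajectories vary around a shared population curve.

Two presets mirror the enrollment regimes of the two Tanzanian antenatal
cohorts that motivate the package: ``study1_preset`` (late enrollment, mean
17.8 weeks — imputing week 14 is mostly *extrapolation*) and
``study2_preset`` (early enrollment, mean 10.0 weeks — *interpolation*).

Generative model, for subject i with enrollment GA e_i:

* population mean curve m(t) = r1 * min(t, c) + r2 * max(t - c, 0), a
  piecewise-linear gestational-weight-gain curve with a changepoint c
  (slow first-trimester gain r1, faster gain r2 thereafter);
* subject slope deviation u_i ~ N(0, slope_heterogeneity^2), linear in t;
* baseline weight B_i ~ N(mu_B + m(e_i) - m(mu_e), sd_B^2), so the cohort
  mean baseline weight equals the preset target mu_B while the *expected*
  weight at a given gestational age does not depend on when a woman
  enrolled (one common curve — this keeps subject-level intercepts
  independent of the visit design);
* the noiseless trajectory is truth_i(t) = c_i + m(t) + u_i t with
  c_i = B_i - m(e_i) - u_i e_i, i.e. truth_i(e_i) = B_i exactly;
* measurements are truth_i(t_ij) + N(0, noise_sd^2) at visit times t_ij =
  e_i, then successive ~4-week intervals until delivery, each follow-up
  visit attended with probability ``attend_prob``.

The trajectory rates, changepoint, noise SD and slope heterogeneity are free
parameters of the generator chosen for physiological plausibility — they are
*not* estimates from any real cohort. Everything is driven by a single seed
and is bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .data_model import WeightDataset
from .errors import DomainError, ParameterError

__all__ = [
    "CohortParams",
    "TruthRecord",
    "study1_preset",
    "study2_preset",
    "simulate_cohort",
    "true_weight",
    "mean_curve",
]


@dataclass(frozen=True)
class CohortParams:
    """Generator parameters; distributions are (mean, sd[, lo, hi])."""

    n_subjects: int
    baseline_weight: tuple[float, float]  # kg
    enroll_ga: tuple[float, float, float, float]  # weeks, truncated normal
    delivery_ga: tuple[float, float, float, float]  # weeks, truncated normal
    visit_interval: tuple[float, float] = (4.0, 0.5)  # mean, jitter sd (weeks)
    attend_prob: float = 0.75  # follow-up visit attendance
    traj_rate1: float = 0.10  # kg/week before the changepoint
    traj_rate2: float = 0.45  # kg/week after the changepoint
    changepoint: float = 13.0  # weeks
    slope_heterogeneity: float = 0.10  # sd of subject rate deviation, kg/week
    noise_sd: float = 1.5  # measurement error sd, kg
    with_covariates: bool = True
    age_mean: float = 23.0  # years, for the covariate sidecar
    primigravida_prob: float = 0.45
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        for name in ("baseline_weight", "visit_interval"):
            if getattr(self, name)[1] < 0:
                raise ParameterError(f"{name} sd must be >= 0")
        for name in ("enroll_ga", "delivery_ga"):
            mean, sd, lo, hi = getattr(self, name)
            if sd < 0 or lo >= hi:
                raise ParameterError(f"invalid truncated-normal spec for {name}")
        if not 0.0 < self.attend_prob <= 1.0:
            raise ParameterError("attend_prob must be in (0, 1]")
        if not 0.0 < self.changepoint < 45.0:
            raise ParameterError("changepoint must lie in (0, 45) weeks")
        if self.slope_heterogeneity < 0 or self.noise_sd < 0:
            raise ParameterError("heterogeneity and noise sds must be >= 0")


def study1_preset(n_subjects: int = 1472, seed: int = 0) -> CohortParams:
    """Late-enrollment cohort: imputing week 14 is mostly extrapolation.

    Enrollment GA ~ N(17.8, 4.4^2) truncated to [4, 28] weeks; baseline
    weight mean 59.7 (SD 11.7) kg; delivery GA ~ N(39.5, 3.5^2) on [28, 44].
    """
    return CohortParams(
        n_subjects=n_subjects,
        baseline_weight=(59.7, 11.7),
        enroll_ga=(17.8, 4.4, 4.0, 28.0),
        delivery_ga=(39.5, 3.5, 28.0, 44.0),
        age_mean=23.9,
        primigravida_prob=0.42,
        seed=seed,
    )


def study2_preset(n_subjects: int = 2131, seed: int = 0) -> CohortParams:
    """Early-enrollment cohort: imputing week 14 is interpolation.

    Enrollment GA ~ N(10.0, 2.4^2) truncated to [4, 14] weeks; baseline
    weight mean 55.6 (SD 11.0) kg; delivery GA ~ N(38.8, 2.7^2) on [28, 44].
    """
    return CohortParams(
        n_subjects=n_subjects,
        baseline_weight=(55.6, 11.0),
        enroll_ga=(10.0, 2.4, 4.0, 14.0),
        delivery_ga=(38.8, 2.7, 28.0, 44.0),
        age_mean=22.6,
        primigravida_prob=0.48,
        seed=seed,
    )


@dataclass(frozen=True)
class TruthRecord:
    """A subject's noiseless trajectory parameters (the simulation truth)."""

    subject_id: str
    intercept: float  # c_i, kg
    rate1: float
    rate2: float
    changepoint: float
    slope_dev: float  # u_i, kg/week


def mean_curve(t, rate1: float, rate2: float, changepoint: float):
    """Population gestational-weight-gain curve m(t), piecewise linear."""
    t = np.asarray(t, dtype=float)
    return rate1 * np.minimum(t, changepoint) + rate2 * np.clip(
        t - changepoint, 0.0, None
    )


def true_weight(truth: TruthRecord, t) -> float:
    """Noiseless weight of a subject at gestational week t in [0, 45]."""
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0) or np.any(arr > 45):
        raise DomainError("gestational week outside [0, 45]")
    val = (
        truth.intercept
        + mean_curve(arr, truth.rate1, truth.rate2, truth.changepoint)
        + truth.slope_dev * arr
    )
    return float(val) if arr.ndim == 0 else val


def _truncated_normal(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def truncated_normal_moments(mean: float, sd: float, lo: float, hi: float):
    """Theoretical (mean, sd) of the truncated normal — calibration oracle."""
    if sd == 0:
        return mean, 0.0
    a, b = (lo - mean) / sd, (hi - mean) / sd
    m, v = truncnorm.stats(a, b, loc=mean, scale=sd, moments="mv")
    return float(m), float(np.sqrt(v))


def simulate_cohort(
    params: CohortParams,
) -> tuple[WeightDataset, list[TruthRecord]]:
    """Generate a cohort and its per-subject noiseless truth records.

    No plausibility clamping is applied at generation time; the
    implausible-weight filter belongs to the downstream cleaning step.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_subjects
    width = max(4, len(str(n)))
    ids = [f"S{i + 1:0{width}d}" for i in range(n)]

    enroll = _truncated_normal(rng, *params.enroll_ga, size=n)
    delivery = _truncated_normal(rng, *params.delivery_ga, size=n)
    delivery = np.maximum(delivery, enroll + 1.0)
    u = rng.normal(0.0, params.slope_heterogeneity, size=n)

    mu_b, sd_b = params.baseline_weight
    mu_e = params.enroll_ga[0]
    m = lambda t: mean_curve(t, params.traj_rate1, params.traj_rate2, params.changepoint)
    baseline = rng.normal(mu_b + m(enroll) - m(mu_e), sd_b, size=n)
    intercept = baseline - m(enroll) - u * enroll

    iv_mean, iv_sd = params.visit_interval
    rows: list[tuple[str, float, float]] = []
    truths: list[TruthRecord] = []
    for i in range(n):
        truth = TruthRecord(
            subject_id=ids[i],
            intercept=float(intercept[i]),
            rate1=params.traj_rate1,
            rate2=params.traj_rate2,
            changepoint=params.changepoint,
            slope_dev=float(u[i]),
        )
        truths.append(truth)
        t = float(enroll[i])
        first = True
        while t <= delivery[i] and t <= 45.0:
            attended = first or rng.random() < params.attend_prob
            noise = rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0
            if attended:
                rows.append((ids[i], t, true_weight(truth, t) + noise))
            first = False
            step = rng.normal(iv_mean, iv_sd) if iv_sd > 0 else iv_mean
            t += max(step, 1.0)

    frame = pd.DataFrame(rows, columns=["subject_id", "gest_week", "weight"])

    covariates = None
    if params.with_covariates:
        age = np.clip(rng.normal(params.age_mean, 4.0, size=n), 15.0, 45.0)
        grav = np.where(
            rng.random(n) < params.primigravida_prob, "primigravida", "multigravida"
        )
        edu_levels = np.array(["0-4y", "5-7y", "8-11y", "12+y"])
        edu = edu_levels[rng.choice(4, size=n, p=[0.06, 0.57, 0.25, 0.12])]
        covariates = pd.DataFrame(
            {"age_years": age, "gravidity": grav, "education": edu},
            index=pd.Index(ids, name="subject_id"),
        )

    return WeightDataset(frame, covariates=covariates), truths


def write_truth_records(truths: Sequence[TruthRecord], path) -> None:
    """Write the truth sidecar CSV (one row per subject)."""
    pd.DataFrame(
        [
            {
                "subject_id": t.subject_id,
                "intercept": t.intercept,
                "rate1": t.rate1,
                "rate2": t.rate2,
                "changepoint": t.changepoint,
                "slope_dev": t.slope_dev,
            }
            for t in truths
        ]
    ).to_csv(path, index=False)
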