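"""Longitudinal pregnancy-weight data: containers, I/O and cleaning.

The central container is :class:`WeightDataset`, an immutable wrapper around
a long-format table with one row per (subject, visit): subject identifier,
gestational age at measurement in decimal weeks, and weight in kg. Optional
subject-level covariates (age, gravidity, education) ride along in a second
table. All cleaning operations (implausible-weight filter, third-trimester
drop, log transform) are pure functions returning new datasets.

Weights are plain kg on the ``natural`` scale; ``transform_log`` switches the
dataset to the ``log`` scale (natural log of kg), used by the log-scale
sensitivity analysis. Gestational age may be supplied either as decimal weeks
or as separate completed-weeks and days columns (converted as weeks + days/7).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    EmptyDatasetError,
    ParameterError,
    ScaleStateError,
    SchemaError,
)

#: canonical long-format column names
CANONICAL_COLUMNS = ("subject_id", "gest_week", "weight")
COVARIATE_COLUMNS = ("age_years", "gravidity", "education")

#: valid gestational-age range in completed weeks
GEST_WEEK_RANGE = (0.0, 45.0)

#: default plausibility bounds for a maternal weight, kg (inclusive)
DEFAULT_MIN_KG = 30.0
DEFAULT_MAX_KG = 120.0

#: default start of the third trimester, completed weeks
DEFAULT_T3_CUTOFF = 28.0


@dataclass(frozen=True)
class WeightMeasurement:
    """One observed weight at one gestational week for one subject."""

    subject_id: str
    gest_week: float
    weight: float


@dataclass(frozen=True)
class SubjectCovariates:
    """Subject-level (time-constant) covariates; any field may be absent."""

    age_years: Optional[float] = None
    gravidity: Optional[str] = None
    education: Optional[str] = None


class WeightDataset:
    """Immutable collection of subjects' repeated weight measurements.

    Parameters
    ----------
    frame
        Long-format DataFrame with columns ``subject_id``, ``gest_week``,
        ``weight``. Rows are validated, de-duplicated on (subject, week)
        keeping the first occurrence, and stored sorted by subject then week.
    covariates
        Optional DataFrame indexed by ``subject_id`` with any of
        ``age_years``, ``gravidity``, ``education``.
    scale
        ``"natural"`` (kg) or ``"log"`` (ln kg).
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        covariates: Optional[pd.DataFrame] = None,
        scale: str = "natural",
        n_dropped_rows: int = 0,
    ):
        if scale not in ("natural", "log"):
            raise ParameterError(f"scale must be 'natural' or 'log', got {scale!r}")
        missing = [c for c in CANONICAL_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(missing)
        df = frame.loc[:, list(CANONICAL_COLUMNS)].copy()
        df["subject_id"] = df["subject_id"].astype(str)
        df["gest_week"] = pd.to_numeric(df["gest_week"])
        df["weight"] = pd.to_numeric(df["weight"])
        if len(df) == 0:
            raise EmptyDatasetError("dataset contains no measurements")

        lo, hi = GEST_WEEK_RANGE
        if not np.isfinite(df["gest_week"]).all():
            raise DomainError("non-finite gestational week")
        if ((df["gest_week"] < lo) | (df["gest_week"] > hi)).any():
            raise DomainError(f"gestational week outside [{lo}, {hi}]")
        if not np.isfinite(df["weight"]).all():
            raise DomainError("non-finite weight")
        if scale == "natural" and (df["weight"] <= 0).any():
            raise DomainError("weight must be positive on the natural scale")

        df = df.sort_values(["subject_id", "gest_week"], kind="mergesort")
        dup = df.duplicated(subset=["subject_id", "gest_week"], keep="first")
        if dup.any():
            warnings.warn(
                f"dropped {int(dup.sum())} duplicate (subject, gest_week) rows, "
                "keeping the first occurrence",
                stacklevel=2,
            )
            df = df.loc[~dup]
        self._frame = df.reset_index(drop=True)
        self._scale = scale
        self.n_dropped_rows = int(n_dropped_rows)

        if covariates is not None:
            cov = covariates.copy()
            cov.index = cov.index.astype(str)
            keep = [c for c in COVARIATE_COLUMNS if c in cov.columns]
            cov = cov.loc[cov.index.isin(self._frame["subject_id"]), keep]
            cov = cov[~cov.index.duplicated(keep="first")].sort_index()
            self._covariates = cov if len(cov.columns) else None
        else:
            self._covariates = None

    # ---------------------------------------------------------------- views

    @property
    def scale(self) -> str:
        return self._scale

    @property
    def n_measurements(self) -> int:
        return len(self._frame)

    @property
    def n_subjects(self) -> int:
        return self._frame["subject_id"].nunique()

    @property
    def subject_ids(self) -> list[str]:
        return list(dict.fromkeys(self._frame["subject_id"]))

    def to_frame(self) -> pd.DataFrame:
        """Copy of the long-format measurement table, sorted by subject/week."""
        return self._frame.copy()

    def covariates_frame(self) -> Optional[pd.DataFrame]:
        return None if self._covariates is None else self._covariates.copy()

    def subject_series(self, subject_id: str) -> pd.DataFrame:
        """A subject's measurements as (gest_week, weight), sorted by week."""
        sel = self._frame.loc[
            self._frame["subject_id"] == str(subject_id), ["gest_week", "weight"]
        ]
        return sel.reset_index(drop=True)

    def subject_covariates(self, subject_id: str) -> SubjectCovariates:
        if self._covariates is None or str(subject_id) not in self._covariates.index:
            return SubjectCovariates()
        row = self._covariates.loc[str(subject_id)]
        return SubjectCovariates(
            age_years=row.get("age_years"),
            gravidity=row.get("gravidity"),
            education=row.get("education"),
        )

    def measurements(self) -> Iterator[WeightMeasurement]:
        for row in self._frame.itertuples(index=False):
            yield WeightMeasurement(row.subject_id, row.gest_week, row.weight)

    def equals(self, other: "WeightDataset") -> bool:
        same_cov = (
            self._covariates is None
            and other._covariates is None
            or (
                self._covariates is not None
                and other._covariates is not None
                and self._covariates.equals(other._covariates)
            )
        )
        return (
            self._scale == other._scale
            and same_cov
            and self._frame.equals(other._frame)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"WeightDataset(n_subjects={self.n_subjects}, "
            f"n_measurements={self.n_measurements}, scale={self._scale!r})"
        )

    def _replace_frame(self, frame: pd.DataFrame, scale: Optional[str] = None):
        """Internal: new dataset with the same covariates (subset to frame)."""
        return WeightDataset(
            frame,
            covariates=self._covariates,
            scale=self._scale if scale is None else scale,
        )


# ------------------------------------------------------------------- I/O


def load_weight_records(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
    delimiter: str = ",",
) -> WeightDataset:
    """Load a long-format delimited table of repeated weight measurements.

    ``column_map`` maps canonical names (``subject_id``, ``gest_week``,
    ``weight``, and optionally ``age_years``, ``gravidity``, ``education``)
    to the file's column names. Instead of ``gest_week`` the map may name
    ``gest_weeks`` and ``gest_days`` columns; gestational age is then
    weeks + days/7. Rows with a missing subject id, gestational week or
    weight are dropped; the count is exposed as ``ds.n_dropped_rows``.
    """
    cmap = dict(column_map or {})
    df = pd.read_csv(path, sep=delimiter, dtype={cmap.get("subject_id", "subject_id"): str})

    def col(name: str) -> str:
        return cmap.get(name, name)

    weeks_days = "gest_weeks" in cmap or "gest_days" in cmap
    required = ["subject_id", "weight"] + (
        ["gest_weeks", "gest_days"] if weeks_days else ["gest_week"]
    )
    missing = [col(n) for n in required if col(n) not in df.columns]
    if missing:
        raise SchemaError(missing)

    out = pd.DataFrame()
    out["subject_id"] = df[col("subject_id")].astype("string")
    out["subject_id"] = out["subject_id"].where(out["subject_id"].str.strip().ne(""), pd.NA)
    if weeks_days:
        weeks = pd.to_numeric(df[col("gest_weeks")], errors="coerce")
        days = pd.to_numeric(df[col("gest_days")], errors="coerce")
        out["gest_week"] = weeks + days / 7.0
    else:
        out["gest_week"] = pd.to_numeric(df[col("gest_week")], errors="coerce")
    out["weight"] = pd.to_numeric(df[col("weight")], errors="coerce")

    valid = out.notna().all(axis=1)
    n_dropped = int((~valid).sum())
    out = out.loc[valid]
    if len(out) == 0:
        raise EmptyDatasetError(f"no valid measurement rows in {path}")

    covariates = None
    cov_cols = [c for c in COVARIATE_COLUMNS if col(c) in df.columns]
    if cov_cols:
        cov = df.loc[valid, [col("subject_id")] + [col(c) for c in cov_cols]].copy()
        cov.columns = ["subject_id"] + cov_cols
        cov["subject_id"] = cov["subject_id"].astype(str)
        covariates = cov.groupby("subject_id").first()
        if "age_years" in covariates.columns:
            covariates["age_years"] = pd.to_numeric(
                covariates["age_years"], errors="coerce"
            )

    return WeightDataset(out, covariates=covariates, n_dropped_rows=n_dropped)


def write_weight_records(
    ds: WeightDataset, path: str | Path, delimiter: str = ","
) -> None:
    """Write the canonical long-format CSV (covariate columns appended)."""
    df = ds.to_frame()
    cov = ds.covariates_frame()
    if cov is not None:
        df = df.join(cov, on="subject_id")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=delimiter, index=False)


# ------------------------------------------------------------ cleaning ops


def filter_implausible(
    ds: WeightDataset,
    min_kg: float = DEFAULT_MIN_KG,
    max_kg: float = DEFAULT_MAX_KG,
) -> tuple[WeightDataset, int]:
    """Drop implausible weights, keeping ``min_kg <= weight <= max_kg``.

    Bounds are inclusive: the exclusion rule is weight < min or weight > max,
    so weights exactly at a bound survive. Subjects left with no measurements
    are removed. Returns the filtered dataset and the number of rows removed.
    Only meaningful on the natural (kg) scale.
    """
    if min_kg >= max_kg:
        raise ParameterError(f"min_kg ({min_kg}) must be < max_kg ({max_kg})")
    if ds.scale != "natural":
        raise ScaleStateError("implausibility bounds are in kg; dataset is log-scale")
    df = ds.to_frame()
    keep = (df["weight"] >= min_kg) & (df["weight"] <= max_kg)
    removed = int((~keep).sum())
    kept = df.loc[keep]
    if len(kept) == 0:
        raise EmptyDatasetError("all measurements removed by plausibility filter")
    return ds._replace_frame(kept), removed


def drop_third_trimester(
    ds: WeightDataset, cutoff_week: float = DEFAULT_T3_CUTOFF
) -> WeightDataset:
    """Remove measurements taken at ``gest_week >= cutoff_week``.

    The third trimester is taken to start at 28 completed weeks by default
    (standard obstetric convention); the cutoff is configurable. Subjects
    emptied by the filter are dropped.
    """
    if cutoff_week <= 0:
        raise ParameterError("cutoff_week must be positive")
    df = ds.to_frame()
    kept = df.loc[df["gest_week"] < cutoff_week]
    if len(kept) == 0:
        raise EmptyDatasetError("all measurements fall at/after the cutoff")
    return ds._replace_frame(kept)


def transform_log(ds: WeightDataset) -> WeightDataset:
    """Replace weight by its natural log; flips the scale flag to ``log``."""
    if ds.scale != "natural":
        raise ScaleStateError("dataset is already on the log scale")
    df = ds.to_frame()
    if (df["weight"] <= 0).any():
        raise DomainError("cannot log-transform nonpositive weights")
    df["weight"] = np.log(df["weight"])
    return ds._replace_frame(df, scale="log")


def back_transform(value):
    """Map a log-scale weight back to kg (naive exp, no bias correction)."""
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DomainError("back_transform requires finite values")
    out = np.exp(arr)
    return float(out) if np.isscalar(value) or out.ndim == 0 else out
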