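"""Time transformations g(t): polynomials and restricted cubic splines.

A :class:`BasisSpec` declares how gestational week enters the regression
models: a raw polynomial of degree 1-3, or a restricted cubic spline (RCS)
with 3-5 knots. Knots are placed at percentiles of the pooled training
gestational weeks — either at equally spaced interior percentiles
(quartiles / quintiles / sextiles for 3 / 4 / 5 knots) or at a user-supplied
fixed-percentile scheme such as (5, 50, 95).

The RCS uses the truncated-power construction in Harrell's parametrization:
for knots t_1 < ... < t_k the nonlinear columns are

    s_j(t) = [ (t - t_j)_+^3
               - (t - t_{k-1})_+^3 (t_k - t_j) / (t_k - t_{k-1})
               + (t - t_k)_+^3 (t_{k-1} - t_j) / (t_k - t_{k-1}) ]
             / (t_k - t_1)^2 ,        j = 1, ..., k-2,

which is twice continuously differentiable everywhere and exactly linear
beyond the boundary knots. Together with the linear column t this yields
k - 1 basis columns (the intercept is handled by the model). Fitted curves
and imputations are invariant to the normalization; only coefficients are
parametrization-specific.

Percentiles use linear interpolation between order statistics (numpy's
default, the "type 7" convention), fixed here for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateKnotsError, ParameterError

#: interior equally spaced percentiles by knot count (quartiles, quintiles,
#: sextiles): 100 * i / (k + 1) for i = 1..k
EQUAL_PERCENTILES = {
    3: (25.0, 50.0, 75.0),
    4: (20.0, 40.0, 60.0, 80.0),
    5: (100 / 6, 200 / 6, 50.0, 400 / 6, 500 / 6),
}

#: the alternative fixed-percentile placements compared in the evaluation grid
FIXED_PERCENTILES = {
    3: (5.0, 50.0, 95.0),
    4: (5.0, 35.0, 65.0, 95.0),
    5: (5.0, 27.5, 50.0, 72.5, 95.0),
}


@dataclass(frozen=True)
class BasisSpec:
    """Declarative description of the time transformation g(t).

    ``kind`` is ``"polynomial"`` (with ``degree`` in 1-3) or ``"rcs"``
    (with ``n_knots`` in 3-5 and a knot ``placement``). For
    ``placement="fixed_percentiles"`` the strictly increasing ``percentiles``
    (in (0, 100)) must be given; ``"equal_percentiles"`` uses the interior
    quartile/quintile/sextile scheme.
    """

    kind: str
    degree: Optional[int] = None
    n_knots: Optional[int] = None
    placement: str = "equal_percentiles"
    percentiles: Optional[tuple[float, ...]] = None

    def __post_init__(self):
        if self.kind == "polynomial":
            if self.degree not in (1, 2, 3):
                raise ParameterError("polynomial degree must be 1, 2 or 3")
        elif self.kind == "rcs":
            if self.n_knots not in (3, 4, 5):
                raise ParameterError("rcs n_knots must be 3, 4 or 5")
            if self.placement not in ("equal_percentiles", "fixed_percentiles"):
                raise ParameterError(f"unknown placement {self.placement!r}")
            if self.placement == "fixed_percentiles":
                pct = self.percentiles
                if pct is None or len(pct) != self.n_knots:
                    raise ParameterError(
                        "fixed_percentiles requires one percentile per knot"
                    )
                pct = tuple(float(p) for p in pct)
                if any(not 0 < p < 100 for p in pct) or any(
                    a >= b for a, b in zip(pct, pct[1:])
                ):
                    raise ParameterError(
                        "percentiles must be strictly increasing within (0, 100)"
                    )
                object.__setattr__(self, "percentiles", pct)
        else:
            raise ParameterError(f"unknown basis kind {self.kind!r}")

    # ------------------------------------------------------------- helpers

    @staticmethod
    def polynomial(degree: int) -> "BasisSpec":
        return BasisSpec(kind="polynomial", degree=degree)

    @staticmethod
    def rcs(
        n_knots: int,
        placement: str = "equal_percentiles",
        percentiles: Optional[Sequence[float]] = None,
    ) -> "BasisSpec":
        return BasisSpec(
            kind="rcs",
            n_knots=n_knots,
            placement=placement,
            percentiles=None if percentiles is None else tuple(percentiles),
        )

    @property
    def n_columns(self) -> int:
        """Basis dimension excluding the intercept."""
        return self.degree if self.kind == "polynomial" else self.n_knots - 1

    @property
    def label(self) -> str:
        if self.kind == "polynomial":
            return {1: "linear", 2: "quadratic", 3: "cubic"}[self.degree]
        if self.placement == "equal_percentiles":
            return f"rcs{self.n_knots}"
        pct = ",".join(f"{p:g}" for p in self.percentiles)
        return f"rcs{self.n_knots}({pct})"

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.kind == "polynomial":
            d["degree"] = self.degree
        else:
            d["n_knots"] = self.n_knots
            d["placement"] = self.placement
            if self.percentiles is not None:
                d["percentiles"] = list(self.percentiles)
        return d

    @staticmethod
    def from_dict(d: dict) -> "BasisSpec":
        known = {"kind", "degree", "n_knots", "placement", "percentiles"}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown basis keys: {sorted(unknown)}")
        pct = d.get("percentiles")
        return BasisSpec(
            kind=d.get("kind", "polynomial"),
            degree=d.get("degree"),
            n_knots=d.get("n_knots"),
            placement=d.get("placement", "equal_percentiles"),
            percentiles=None if pct is None else tuple(pct),
        )


@dataclass(frozen=True)
class KnotVector:
    """Strictly increasing knot locations in gestational weeks."""

    knots: tuple[float, ...]

    def __post_init__(self):
        k = tuple(float(x) for x in self.knots)
        if len(k) < 3 or len(k) > 5:
            raise ParameterError("knot vector must have 3-5 knots")
        if any(a >= b for a, b in zip(k, k[1:])):
            raise DegenerateKnotsError(f"knots not strictly increasing: {k}")
        object.__setattr__(self, "knots", k)

    def __len__(self) -> int:
        return len(self.knots)


def knots_from_percentiles(times, spec: BasisSpec) -> KnotVector:
    """Empirical percentile knots from the pooled training gestational weeks.

    Uses the spec's placement scheme; percentiles are computed with linear
    interpolation (numpy default). Tied knot values — e.g. fewer distinct
    times than knots — raise :class:`DegenerateKnotsError`.
    """
    if spec.kind != "rcs":
        raise ParameterError("knots are only defined for rcs bases")
    t = np.asarray(times, dtype=float)
    t = t[np.isfinite(t)]
    if spec.placement == "equal_percentiles":
        pct = EQUAL_PERCENTILES[spec.n_knots]
    else:
        pct = spec.percentiles
    if len(np.unique(t)) < spec.n_knots:
        raise DegenerateKnotsError(
            f"{len(np.unique(t))} distinct times cannot support {spec.n_knots} knots"
        )
    knots = np.percentile(t, pct, method="linear")
    if len(np.unique(knots)) != len(knots):
        raise DegenerateKnotsError(f"tied percentile knots: {knots.tolist()}")
    return KnotVector(tuple(knots.tolist()))


def _rcs_columns(t: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Nonlinear RCS columns s_1..s_{k-2} (Harrell normalization)."""
    k = np.asarray(knots, dtype=float)
    nk = len(k)
    norm = (k[-1] - k[0]) ** 2
    denom = k[-1] - k[-2]

    def tp3(x):  # truncated third power
        return np.clip(x, 0.0, None) ** 3

    cols = []
    for j in range(nk - 2):
        s = (
            tp3(t - k[j])
            - tp3(t - k[-2]) * (k[-1] - k[j]) / denom
            + tp3(t - k[-1]) * (k[-2] - k[j]) / denom
        ) / norm
        cols.append(s)
    return np.column_stack(cols)


def design_matrix(
    times, spec: BasisSpec, knots: Optional[KnotVector] = None
) -> np.ndarray:
    """Evaluate g(t) row-wise for a vector of gestational weeks.

    Returns an (n, spec.n_columns) array: powers t, t^2, ... for polynomials;
    (t, s_1(t), ..., s_{k-2}(t)) for an RCS. ``knots`` must be supplied iff
    the spec is an RCS.
    """
    t = np.asarray(times, dtype=float).ravel()
    if spec.kind == "polynomial":
        if knots is not None:
            raise ParameterError("knots are not used by polynomial bases")
        return np.column_stack([t**p for p in range(1, spec.degree + 1)])
    if knots is None:
        raise ParameterError("rcs basis requires a knot vector")
    if len(knots) != spec.n_knots:
        raise ParameterError(
            f"knot vector has {len(knots)} knots, spec expects {spec.n_knots}"
        )
    return np.column_stack([t, _rcs_columns(t, knots.knots)])


def design_row(
    t: float, spec: BasisSpec, knots: Optional[KnotVector] = None
) -> np.ndarray:
    """g(t) for a single gestational week (1-D array of length n_columns)."""
    return design_matrix([t], spec, knots)[0]
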