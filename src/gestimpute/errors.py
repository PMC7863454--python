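"""Exception hierarchy for gestimpute.

Every error raised by the package derives from :class:`GestimputeError`,
so callers can catch one type at a pipeline boundary. Convergence failure
of a model fit is an expected, reportable outcome (a grid cell rendered
"N/A"), not a crash, and carries the offending basis specification.
"""

from __future__ import annotations


class GestimputeError(Exception):
    """Base class for all package errors."""


class SchemaError(GestimputeError):
    """Input table is missing required (mapped) columns."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(f"missing required columns: {', '.join(self.missing)}")


class EmptyDatasetError(GestimputeError):
    """No valid measurement rows remain after validation."""


class DomainError(GestimputeError, ValueError):
    """A value lies outside its scientific domain (e.g. weight <= 0)."""


class ParameterError(GestimputeError, ValueError):
    """Invalid argument combination (e.g. min_kg >= max_kg)."""


class ScaleStateError(GestimputeError):
    """Operation applied on the wrong weight scale (natural vs log)."""


class NoDataError(GestimputeError):
    """A subject has too few training measurements for the imputer."""


class UnknownSubjectError(GestimputeError):
    """Subject absent from a fitted model's residual store."""


class DegenerateKnotsError(GestimputeError):
    """Percentile knots are tied or fewer distinct times than knots."""


class ConvergenceFailure(GestimputeError):
    """Model optimizer failed to converge for a basis specification."""

    def __init__(self, message: str, spec=None):
        self.spec = spec
        super().__init__(message)


class InfeasibleSplitError(GestimputeError):
    """Fewer eligible subjects than the requested testing-set size."""

    def __init__(self, eligible: int, requested: int):
        self.eligible = eligible
        self.requested = requested
        super().__init__(
            f"only {eligible} subjects eligible for a testing set of {requested}"
        )


class ConfigError(GestimputeError):
    """Run-configuration file violates the schema."""


class PopulationOnlyWarning(UserWarning):
    """Imputation fell back to the population (fixed-effects) curve."""
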