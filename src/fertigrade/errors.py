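"""Exception hierarchy for the grading-system pipeline."""


class FertigradeError(Exception):
    """Base class for all package errors."""


class CohortError(FertigradeError):
    """Malformed cohort input or cleaning-rule violation."""


class ScreenError(FertigradeError):
    """Invalid feature-screening request."""


class DiscretizationError(FertigradeError):
    """Invalid discretization input (empty labels, bad cut, empty interval)."""


class WeightError(FertigradeError):
    """Degenerate importance vector or invalid weighting request."""


class GradeError(FertigradeError):
    """Score outside [1, 4] or unresolved grade threshold."""


class StratificationError(FertigradeError):
    """Total-score stratification could not produce the requested grades."""


class SystemSchemaError(FertigradeError):
    """Scoring-system file is malformed or has an unsupported schema version."""


class SyntheticConfigError(FertigradeError):
    """Inconsistent synthetic-cohort configuration."""


class AuditError(FertigradeError):
    """Record-exclusion arithmetic is inconsistent."""
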