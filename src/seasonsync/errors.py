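"""Exception hierarchy shared across the package."""


class SeasonSyncError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SeasonSyncError):
    """Invalid generator, schedule, or pipeline configuration."""


class DataIntegrityError(SeasonSyncError):
    """Input records violate referential integrity (e.g. unknown patient)."""


class InsufficientDataError(SeasonSyncError):
    """Too few observations for the requested computation."""


class DegenerateBaselineError(SeasonSyncError):
    """Fitted baseline is ~0 at some month; percentage deviation undefined."""


class ShapeError(SeasonSyncError):
    """Series does not span the required whole number of years."""


class DegenerateVarianceError(SeasonSyncError):
    """Zero pooled variance (t test) or zero-variance regressor."""


class EmptyTableError(SeasonSyncError):
    """No admission records to tabulate."""


class EmptyProfileError(SeasonSyncError):
    """Synchronized profile has no defined month."""


class ComparisonError(SeasonSyncError):
    """Simulation results are not comparable (mismatched configurations)."""
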