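"""Exception hierarchy shared across the package."""


class HteForestError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(HteForestError):
    """A required column or dictionary entry is missing or malformed."""


class RowParseError(HteForestError):
    """A row holds an unparseable value for a typed column."""

    def __init__(self, message, row=None, column=None):
        super().__init__(message)
        self.row = row
        self.column = column


class HarmonizationError(HteForestError):
    """Two cohorts cannot be pooled because their dictionaries disagree."""

    def __init__(self, message, discordant=()):
        super().__init__(message)
        self.discordant = tuple(discordant)


class StratificationError(HteForestError):
    """A study x arm stratum is empty or too small to split."""


class DomainError(HteForestError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class SingularFitError(HteForestError):
    """A regression fit is degenerate (e.g. constant regressor)."""


class UndefinedEffectError(HteForestError):
    """A treatment-effect estimate is undefined (an arm is absent/empty)."""


class ConfigurationError(HteForestError):
    """A configuration object violates its invariants."""


class FitError(HteForestError):
    """Model fitting cannot proceed (e.g. empty estimation sample)."""


class UnassignableRecordError(HteForestError):
    """A record cannot be routed through a tree (missing splitting covariate)."""


class NoPredictionError(HteForestError):
    """Every tree in the ensemble had to be skipped for a record."""


class StageError(HteForestError):
    """A pipeline stage failed; carries the stage name for the manifest."""

    def __init__(self, stage, original):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original
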