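"""Exception hierarchy shared across the pipeline."""


class GraceRecalError(Exception):
    """Base class for all package errors."""


class SchemaError(GraceRecalError):
    """A required column is missing or malformed in an input table."""


class InputError(GraceRecalError):
    """An input file or table is unusable (empty, unreadable)."""


class ConfigError(GraceRecalError):
    """A configuration value violates its constraints."""


class PreconditionError(GraceRecalError):
    """An operation was called on inputs that violate its preconditions."""


class SeparationError(GraceRecalError):
    """Perfect separation detected while fitting a logistic model."""


class RankError(GraceRecalError):
    """The design matrix is rank deficient."""


class DegenerateOutcomeError(GraceRecalError):
    """The outcome is constant (all events or all non-events)."""


class UndefinedStatisticError(GraceRecalError):
    """A statistic is undefined for the given data (e.g. zero denominator)."""


class PipelineError(GraceRecalError):
    """A pipeline stage failed; message carries the stage name and counts."""
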