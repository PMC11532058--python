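"""Exception hierarchy for the fQRS pipeline.

Every stage raises a subclass of :class:`FqrsError` so that the pipeline
driver can distinguish stage failures from programming errors.
"""


class FqrsError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(FqrsError, ValueError):
    """A generator or feature parameter violates its documented domain."""


class TooShortError(FqrsError, ValueError):
    """Record too short for the requested operation."""


class NoBeatsError(FqrsError, ValueError):
    """No heartbeats could be detected in the record."""


class DegenerateRecordError(FqrsError, ValueError):
    """The record survived detection but no usable beat remains."""


class NoAnchorError(FqrsError, ValueError):
    """PRSA found no anchor points (monotone non-increasing segment)."""


class ZeroEnergyError(FqrsError, ValueError):
    """All decomposition modes carry zero energy."""


class DegenerateTrainingError(FqrsError, ValueError):
    """Training labels collapse to a single class."""


class MissingLeadError(FqrsError, KeyError):
    """A required ECG lead is absent from the input."""


class NoFeasibleThresholdError(FqrsError, ValueError):
    """No candidate cutoff satisfies the specificity constraint."""


class InconsistentCalendarError(FqrsError, ValueError):
    """A patient's event calendar violates its ordering invariants."""


class ConfigError(FqrsError, ValueError):
    """Invalid pipeline or scenario configuration."""


class DegenerateTableError(FqrsError, ValueError):
    """A contingency table has a zero margin."""


class InestimableError(FqrsError, ValueError):
    """A regression cannot be estimated (no events or constant covariate)."""


class EmptyModelError(FqrsError, ValueError):
    """No covariate passed univariable screening."""


class FormatError(FqrsError, ValueError):
    """An ECG file does not conform to the expected format."""
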