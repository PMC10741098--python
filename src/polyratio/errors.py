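"""Exception hierarchy for the polyratio pipeline.

Every error raised deliberately by the package derives from
:class:`PolyratioError`, so callers (and the CLI) can distinguish pipeline
failures from programming errors.
"""


class PolyratioError(Exception):
    """Base class for all polyratio errors."""


class ConfigError(PolyratioError):
    """A simulation or run configuration field is invalid.

    The message names the offending field.
    """


class FormatError(PolyratioError):
    """An external table violates its format contract.

    Where possible the message includes the file path and 1-based line
    number of the offending record.
    """


class InputError(PolyratioError):
    """In-memory inputs violate an operation precondition (empty table,
    misaligned join, missing column)."""


class FilterError(PolyratioError):
    """A filtering step removed every row."""


class SpanTooSmallError(PolyratioError):
    """The LOESS window implied by the span cannot support the requested
    local polynomial degree."""


class ExtrapolationError(PolyratioError):
    """Prediction was requested outside the range of the training
    predictors with extrapolation set to ``"error"``."""


class InsufficientDataError(PolyratioError):
    """A statistical comparison group has fewer than two members."""
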