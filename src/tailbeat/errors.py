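"""Exception hierarchy shared across the package.

Every error raised by tailbeat derives from :class:`TailbeatError`, so callers
(and the CLI) can distinguish pipeline failures from programming errors.
"""


class TailbeatError(Exception):
    """Base class for all tailbeat errors."""


class ParameterError(TailbeatError, ValueError):
    """An input parameter violates its contract; message names the field."""


class FormatError(TailbeatError, ValueError):
    """A file does not conform to the expected dialect; message carries a row
    number where one is known."""


class UnknownConditionError(TailbeatError, KeyError):
    """A condition/preset name is not in the registry; message lists valid names."""


class DegenerateSignalError(TailbeatError, ValueError):
    """A signal has zero variance, so correlation statistics are undefined."""


class NotRhythmicError(TailbeatError, ValueError):
    """No significant autocorrelation peak: a locomotor period cannot be read."""


class InsufficientEventsError(TailbeatError, ValueError):
    """Too few burst events to compute an alternation statistic."""


class IllConditionedFitError(TailbeatError, ValueError):
    """The dose-response design cannot constrain the fit (e.g. too few doses)."""


class OutOfRangeError(TailbeatError, ValueError):
    """A required feature (e.g. a zero crossing) lies outside the recorded range."""
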