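"""Exception hierarchy for the analysis pipeline.

All library errors derive from :class:`EmgCycleError` so callers can catch
pipeline failures without masking programming errors.
"""


class EmgCycleError(Exception):
    """Base class for all errors raised by this package."""


class InvalidProtocolError(EmgCycleError, ValueError):
    """A movement protocol violates its invariants (e.g. bpm <= 0)."""


class ConfigurationError(EmgCycleError, ValueError):
    """A processing parameter is inconsistent with the data it is applied to."""


class SamplingRateError(ConfigurationError):
    """A sampling rate is too low for the requested operation."""


class AlignmentError(EmgCycleError, ValueError):
    """Two streams that must share a time base have mismatched lengths."""


class InsufficientDataError(EmgCycleError, ValueError):
    """A record is too short for the requested operation."""


class StageOrderError(EmgCycleError, ValueError):
    """An envelope-processing stage was applied out of order."""


class NoCyclesError(EmgCycleError, ValueError):
    """No complete movement cycle could be delimited in an angle trace."""


class ParseError(EmgCycleError, ValueError):
    """An input file failed validation; the message names the file and row."""


class EmptyResultError(EmgCycleError, RuntimeError):
    """A pipeline run produced no usable trials."""
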