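"""Exception hierarchy for gaitevents.

All package errors derive from :class:`GaitError` so callers can catch one
base class at pipeline boundaries (the CLI maps them to exit code 2).
"""


class GaitError(Exception):
    """Base class for all gaitevents errors."""


class ParseError(GaitError):
    """A CSV file could not be parsed; the message names the offending row."""


class SamplingError(GaitError):
    """Timestamps are inconsistent with the declared sampling frequency."""


class FormatError(GaitError):
    """A file is syntactically valid CSV but semantically malformed."""


class LengthError(GaitError):
    """An input sequence is too short for the requested operation."""


class ShapeError(GaitError):
    """Input sequences have mismatched lengths/shapes."""


class ParameterError(GaitError):
    """A parameter is outside its valid range."""


class DegenerateSignalError(GaitError):
    """The signal is degenerate for the operation (e.g. all-zero jerk)."""


class IntervalError(GaitError):
    """A sample interval is invalid or too short."""


class DetectionError(GaitError):
    """No trough candidate satisfied the event criterion.

    Carries the candidate list so the caller may relax thresholds.
    """

    def __init__(self, message, candidates=None):
        super().__init__(message)
        self.candidates = list(candidates) if candidates is not None else []


class SampleSizeError(GaitError):
    """Too few observations for the requested statistic."""


class ConfigError(GaitError):
    """Configuration file contains unknown keys or invalid values."""
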