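"""Exception hierarchy for burstclass.

All package errors derive from :class:`BurstClassError` so callers can catch
one base class at pipeline boundaries.
"""


class BurstClassError(Exception):
    """Base class for all burstclass errors."""


class SchemaError(BurstClassError):
    """A mandatory column is missing or the column mapping is invalid."""


class ParseError(BurstClassError):
    """A cell could not be parsed; carries the offending row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class LabelError(BurstClassError):
    """An observation refers to a behaviour outside the ethogram."""


class ShapeError(BurstClassError):
    """Axis sequences have mismatched lengths."""


class InsufficientDataError(BurstClassError):
    """Too few samples for the requested statistic (need >= 2)."""


class UndefinedOrientationError(BurstClassError):
    """Posture angles are undefined for an all-zero mean acceleration vector."""


class WindowTooLargeError(BurstClassError):
    """Window size exceeds the burst length."""


class StratificationError(BurstClassError):
    """A class has too few bursts to split (need >= 2 per class)."""


class DegenerateTrainingError(BurstClassError):
    """Training data contains fewer than two classes."""


class ProbabilityError(BurstClassError):
    """A probability vector is malformed (negative or does not sum to 1)."""


class VoteError(BurstClassError):
    """Majority vote requested on an empty window sequence."""


class UndefinedKappaError(BurstClassError):
    """Cohen's kappa undefined because expected agreement equals 1."""


class FitError(BurstClassError):
    """Too few points to fit the performance smoother."""


class DegenerateIntervalError(BurstClassError):
    """Consecutive GPS fixes share a timestamp; speed undefined."""


class ConfigError(BurstClassError):
    """Invalid run configuration or unknown behaviour class."""
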