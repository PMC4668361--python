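"""Exception hierarchy for the bacterial-display toolkit."""


class BadDisplayError(Exception):
    """Base class for all toolkit errors."""


class InvalidAlphabetError(BadDisplayError):
    """A sequence contains characters outside the amino-acid alphabet."""


class UnalignableSequenceError(BadDisplayError):
    """Alignment score against the numbering reference fell below the floor."""


class IncompatibleChainError(BadDisplayError):
    """Operands belong to different chain classes (heavy vs light)."""


class OutOfRangeError(BadDisplayError):
    """A Kabat position falls outside the coverage of a region map."""


class MissingAnnotationError(BadDisplayError):
    """A required per-position annotation (e.g., burial) is absent."""


class LibraryParseError(BadDisplayError):
    """A library file row could not be parsed."""


class ConfigError(BadDisplayError):
    """Invalid or self-contradictory configuration."""


class EmptyGateError(BadDisplayError):
    """A sort gate retained zero cells; analyze more cells or widen the gate."""


class DegenerateRatioError(BadDisplayError):
    """Marker colonies equal total colonies; the marker ratio is infinite."""


class EmptyPlateError(BadDisplayError):
    """A plate count with zero total colonies cannot yield a ratio."""


class UndefinedEnrichmentError(BadDisplayError):
    """Fold enrichment is undefined for a zero input ratio."""


class InsufficientRoundsError(BadDisplayError):
    """Enrichment calls need at least two selection rounds."""


class InsufficientDataError(BadDisplayError):
    """Too few points for the requested calibration or fit."""


class NoTransitionError(BadDisplayError):
    """No melt transition exceeded the prominence threshold."""


class FitFailureError(BadDisplayError):
    """Nonlinear fit failed to converge from every starting point."""
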