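"""Exception hierarchy for plate processing."""


class QplexError(Exception):
    """Base class for all package errors."""


class FormatError(QplexError):
    """An input file does not have the expected structure (e.g. missing sheet)."""


class ValidationError(QplexError):
    """Input parsed but violates a content constraint (duplicates, missing wells...)."""


class StageError(QplexError):
    """A pipeline stage cannot proceed (e.g. no background wells, plate unusable)."""


class StabilityError(StageError):
    """No housekeeping gene satisfies the fold-change stability criterion."""


class FitError(QplexError):
    """A model fit cannot be computed for structural reasons."""
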