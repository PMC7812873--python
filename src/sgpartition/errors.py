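"""Exception hierarchy for sgpartition."""


class SGPartitionError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(SGPartitionError, ValueError):
    """An argument violates a documented precondition."""


class FitError(SGPartitionError):
    """Too few usable points, or a degenerate design, for a curve fit."""


class SaturationError(SGPartitionError):
    """Enrichment at or above the curve cap cannot be inverted."""


class UndefinedFractionError(SGPartitionError):
    """A cell with zero cytoplasmic spots has no in-granule fraction."""


class EmptyDatasetError(SGPartitionError):
    """No valid cells (or rows) remain after filtering."""


class GenerationError(SGPartitionError):
    """Sequence generation could not satisfy the motif constraints."""


class SequenceError(SGPartitionError, ValueError):
    """A sequence or motif contains characters outside the IUPAC alphabet."""


class UndefinedCorrelationError(SGPartitionError):
    """Correlation is undefined because one variable has zero variance."""
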