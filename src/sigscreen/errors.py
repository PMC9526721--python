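"""Exception hierarchy for sigscreen.

Every failure mode promised by the public API raises one of these, so callers
(and the CLI) can distinguish bad input from bad data from empty results.
"""


class SigscreenError(Exception):
    """Base class for all sigscreen errors."""


class FormatError(SigscreenError):
    """A file or table violates the expected format (duplicates, bad cells...)."""


class AnnotationError(SigscreenError):
    """Sample annotation does not cover the expression matrix."""


class InsufficientDataError(SigscreenError):
    """Too few samples/genes for the requested operation."""


class ZeroVarianceError(SigscreenError):
    """A gene or sample has zero variance where variation is required."""


class MappingError(SigscreenError):
    """Probe-to-gene mapping does not intersect the dataset."""


class EmptySignatureError(SigscreenError):
    """A query signature has an empty up- or down-tag list."""


class UnitMismatchError(SigscreenError):
    """Physical quantities carry inconsistent unit tags."""


class ConfigError(SigscreenError):
    """Pipeline configuration is missing, malformed, or has unknown keys."""
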