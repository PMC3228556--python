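"""Exception hierarchy shared across the package."""


class AlignHushError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AlignHushError):
    """A file does not conform to the expected text format."""


class TruncationError(FormatError):
    """A file declares more content than it contains."""


class VersionError(FormatError):
    """An interchange file carries an unsupported format version."""


class AnnotationError(AlignHushError):
    """Per-column annotations are inconsistent with the alignment."""


class EmptyProfileError(AlignHushError):
    """No match columns survive column assignment."""


class EstimationError(AlignHushError):
    """A table or distribution cannot be estimated from the given data."""


class CalibrationError(AlignHushError):
    """Score statistics cannot be calibrated (e.g. degenerate sample)."""


class SamplingError(AlignHushError):
    """A random-database request cannot be satisfied from the pool."""


class BenchmarkError(AlignHushError):
    """A benchmark input is unusable (e.g. no true relations)."""


class ContractViolation(AlignHushError):
    """An internal consistency contract was violated by the caller."""
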