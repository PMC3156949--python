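"""Exception hierarchy shared across the package."""


class ChromobandError(Exception):
    """Base class for all chromoband errors."""


class ValidationError(ChromobandError, ValueError):
    """Input violates a documented precondition or invariant."""


class CoordinateRangeError(ValidationError):
    """A genomic coordinate lies outside the chromosome."""


class ParseError(ChromobandError, ValueError):
    """A file could not be parsed; the message names the offending line(s)."""


class SegmentationError(ChromobandError):
    """No single chromatid object could be segmented from the image."""


class MarkerMissingError(ChromobandError):
    """The centromere marker channel is empty."""


class CalibrationError(ChromobandError):
    """The scan cannot be calibrated (e.g. centromere at an arm end)."""


class DegenerateInputError(ChromobandError):
    """An input with zero variance (or similar) makes the statistic undefined."""


class SchemeMismatchError(ValidationError):
    """Two window tracks do not share a window scheme."""
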