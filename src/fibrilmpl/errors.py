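"""Exception hierarchy shared across the package."""


class FibrilMplError(Exception):
    """Base class for all package-specific errors."""


class ImageFormatError(FibrilMplError):
    """Raised for images that cannot be interpreted as single-channel grayscale."""


class SelectionParseError(FibrilMplError):
    """Raised when a selection file cannot be parsed; message carries the line number."""


class SelectionValidationError(FibrilMplError):
    """Raised when parsed selection fields violate geometric invariants."""


class SamplingError(FibrilMplError):
    """Raised when a selection yields no usable slices."""


class CalibrationError(FibrilMplError):
    """Raised when the standard calibration cannot be computed or is non-physical."""


class AnalysisError(FibrilMplError):
    """Raised when a statistic cannot be computed from the available measurements."""


class PhantomSpecError(FibrilMplError):
    """Raised for invalid synthetic-phantom specifications."""
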