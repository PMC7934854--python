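"""Exception types shared across the package."""


class RetmosaicError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(RetmosaicError, ValueError):
    """An input or specification violates a stated invariant."""


class DegenerateHistogramError(RetmosaicError):
    """Thresholding was requested on a histogram with fewer than two classes."""


class InsufficientDataError(RetmosaicError):
    """Too few observations to compute a robust estimate."""


class UndefinedRatioError(RetmosaicError):
    """A ratio was requested with a zero denominator."""
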