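"""Exception hierarchy shared across the package."""


class RainbowSpecError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(RainbowSpecError, ValueError):
    """A configuration value or algorithm parameter is out of range."""


class InvalidInputError(RainbowSpecError, ValueError):
    """An input array has the wrong shape, dtype or content."""


class DegenerateInputError(RainbowSpecError, ValueError):
    """The input is formally valid but carries no usable signal
    (e.g. a single-level histogram, a zero-variance row)."""


class LabelError(RainbowSpecError, ValueError):
    """Sample labels are missing, inconsistent or unknown."""


class UnsupportedConfigurationError(RainbowSpecError, ValueError):
    """The requested combination of inputs and settings is not supported."""


class NonlinearityCertificateError(RainbowSpecError, RuntimeError):
    """A generated population failed its not-linearly-separable check."""


class SegmentationError(RainbowSpecError, RuntimeError):
    """No usable object could be segmented from the image.

    Carries the diagnostic binary mask (possibly empty) that the
    pipeline produced before giving up.
    """

    def __init__(self, message, mask=None):
        super().__init__(message)
        self.mask = mask
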