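"""Exception hierarchy for mrmar."""


class MrmarError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MrmarError, ValueError):
    """An input violates a documented precondition."""


class DegenerateHistogramError(ValidationError):
    """Raised when an image has no intensity spread, so no threshold exists."""


class ImageIOError(MrmarError, IOError):
    """Raised when an image file cannot be read or written."""
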