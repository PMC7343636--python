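"""Exception hierarchy shared across the pipeline."""


class SccPipeError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SccPipeError, ValueError):
    """Invalid configuration, metadata, or manifest content."""


class ManifestError(ValidationError):
    """Malformed or inconsistent sample manifest."""


class UnsupportedFormatError(SccPipeError, ValueError):
    """Image file is not a grayscale multi-page stack."""


class DegenerateInputError(SccPipeError, ValueError):
    """Input carries no usable signal (e.g. constant image)."""


class PlacementError(SccPipeError, RuntimeError):
    """Phantom geometry cannot be placed under the configured constraints."""


class UndefinedBaselineError(SccPipeError, ZeroDivisionError):
    """Pre-treatment value is zero, so percent-of-pre is undefined."""
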