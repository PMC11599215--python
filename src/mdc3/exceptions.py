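"""Exception hierarchy.

All errors derive from :class:`MDC3Error` (itself a ``ValueError``) so callers
can catch either the package root or builtin validation errors.
"""


class MDC3Error(ValueError):
    """Base class for all mdc3 errors."""


class InvalidParameterError(MDC3Error):
    """A configuration parameter violates its documented domain."""


class InvalidInputError(MDC3Error):
    """Input data violate a precondition (shape, length, range)."""


class InvalidScaleError(InvalidInputError):
    """Requested window length is not a usable scale (s < 1 or s > signal length)."""


class DegenerateWindowError(InvalidInputError):
    """A window is too short for the requested polynomial detrending."""


class DegenerateSignalError(InvalidInputError):
    """A signal has zero (detrended) variance, so normalized coupling is undefined."""


class NoValidScalesError(InvalidInputError):
    """Every requested frequency was dropped; no scale fits the signal."""


class DegenerateMatrixError(InvalidInputError):
    """A matrix has zero spread over the entries selected for standardization."""


class FormatError(MDC3Error):
    """A delimited-text file could not be parsed into the expected structure."""
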