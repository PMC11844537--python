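"""Exception types shared across the package."""


class PvatGrnError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PvatGrnError, ValueError):
    """A parameter violates its documented domain (negative count, bad fraction, ...)."""


class ConvergenceError(PvatGrnError, RuntimeError):
    """An iterative solver failed to reach tolerance within its iteration budget."""


class FormatError(PvatGrnError, ValueError):
    """An on-disk input is malformed (e.g. sidecar/matrix dimension mismatch)."""


class DivisionError(PvatGrnError, ZeroDivisionError):
    """A ratio was requested with a zero denominator and no stabilizing epsilon."""
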