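"""Exception hierarchy.

All physically impossible inputs raise :class:`DomainError`; malformed or
incomplete configuration raises :class:`ConfigurationError`; fitting and
numerical failures raise :class:`FitError` / :class:`NumericalError` so that
callers can distinguish "your numbers are wrong" from "the solver gave up".
"""


class AquafluxError(Exception):
    """Base class for all package errors."""


class DomainError(AquafluxError, ValueError):
    """Input outside the physical domain of an operation."""


class ConfigurationError(AquafluxError, ValueError):
    """Incomplete or inconsistent object configuration."""


class NumericalError(AquafluxError, RuntimeError):
    """Numerical integration or root finding failed; carries diagnostics."""


class FitError(AquafluxError, RuntimeError):
    """A least-squares fit failed to converge or the data are degenerate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class InversionError(AquafluxError, ValueError):
    """Calibration inversion ambiguous or impossible; names both roots."""

    def __init__(self, message, roots=()):
        super().__init__(message)
        self.roots = tuple(roots)


class DesignError(AquafluxError, ValueError):
    """Regression design degenerate (collinear or too few points)."""


class RangeError(AquafluxError, ValueError):
    """Requested value outside a precomputed grid/range."""


class ParseError(AquafluxError, ValueError):
    """Malformed input file; message carries the offending line/column."""
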