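"""Exception hierarchy.

All errors raised on bad user input derive from :class:`FluorobindError`
so callers can catch one base class; the subclasses distinguish the
failure modes the analyses can hit (bad configuration, degenerate data,
non-physical fit results).
"""


class FluorobindError(Exception):
    """Base class for all package errors."""


class ValidationError(FluorobindError, ValueError):
    """Input violates a documented precondition."""


class ConfigurationError(FluorobindError, ValueError):
    """A parameter set is internally inconsistent or incomplete."""


class DegenerateInputError(FluorobindError, ValueError):
    """Input is formally valid but makes the quantity undefined."""


class InsufficientDataError(FluorobindError, ValueError):
    """Too few usable observations for the requested fit."""


class NonPhysicalFitError(FluorobindError, RuntimeError):
    """A fit converged to a parameter region the model forbids.

    Carries the raw regression coefficients so the caller can inspect
    what went wrong.
    """

    def __init__(self, message: str, slope: float | None = None,
                 intercept: float | None = None):
        super().__init__(message)
        self.slope = slope
        self.intercept = intercept


class MissingBandError(FluorobindError, RuntimeError):
    """A required spectral band was not found in its search window."""

    def __init__(self, message: str, which: str = ""):
        super().__init__(message)
        self.which = which
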