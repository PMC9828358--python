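"""Exception hierarchy shared by all tyrspec modules."""


class TyrspecError(Exception):
    """Base class for all tyrspec errors."""


class ValidationError(TyrspecError, ValueError):
    """An input violates a documented precondition or invariant."""


class FitError(TyrspecError, RuntimeError):
    """A fitting routine could not produce a usable result."""


class FitFailureError(FitError):
    """No optimizer start converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class UndefinedAnisotropyError(TyrspecError, ZeroDivisionError):
    """The anisotropy denominator Ivv + 2*G*Ivh is not positive."""


class NoCACError(FitError):
    """The tension titration shows no surface activity / no breakpoint."""


class NoBandsError(TyrspecError, ValueError):
    """Band extraction was asked for on an all-zero lifetime distribution."""


class MemFitError(FitError):
    """The maximum-entropy fit could not reach its chi-square target."""

    def __init__(self, message: str, chi2_red: float | None = None):
        super().__init__(message)
        self.chi2_red = chi2_red
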