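"""Exception hierarchy shared across the package."""


class GevitraceError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(GevitraceError, ValueError):
    """An argument violates a documented precondition."""


class InvalidTraceError(GevitraceError, ValueError):
    """A trace fails a structural requirement (kind, baseline, sampling)."""


class WindowTooShortError(GevitraceError, ValueError):
    """An analysis window does not fit inside the available data."""


class FitError(GevitraceError, RuntimeError):
    """A nonlinear fit failed to converge or is degenerate.

    Carries the residual diagnostics (if any) on ``.diagnostics``.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UndefinedSNRError(GevitraceError, ZeroDivisionError):
    """SNR requested on a trace with zero baseline noise."""


class DegenerateLikelihoodError(GevitraceError, ValueError):
    """Log-likelihood detection requested at d' <= 0 (constant likelihood)."""


class InsufficientTrialsError(GevitraceError, ValueError):
    """A statistical test requires more trials than were provided."""


class EmptyReportError(GevitraceError, ValueError):
    """No spikes could be located, so no detection report can be built."""


class UndefinedVelocityError(GevitraceError, ValueError):
    """Conduction velocity requested with no spread in peak delays."""


class InvalidReferenceError(GevitraceError, ValueError):
    """A soma reference is missing or has zero amplitude."""


class ParseError(GevitraceError, ValueError):
    """A trace table or config file is malformed; message names the row."""
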