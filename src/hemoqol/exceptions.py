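"""Exception hierarchy shared by all hemoqol modules."""


class HemoqolError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HemoqolError, ValueError):
    """A file does not parse in the declared dialect (non-uniform sampling, fs <= 0, ...)."""


class ValidationError(HemoqolError, ValueError):
    """An input violates a documented precondition (out-of-range height, level 6 EQ-5D, ...)."""


class NoBeatsError(HemoqolError):
    """No cardiac beats can be detected (flatline or near-flatline trace)."""


class DegenerateBeatError(HemoqolError):
    """A single beat is too short or malformed to yield fiducial points."""


class InsufficientDataError(HemoqolError):
    """Fewer observations than the operation's stated minimum."""


class CannotComputeError(HemoqolError):
    """A derived quantity is undefined for this beat (e.g. stroke volume without a notch)."""


class PatientExclusionError(HemoqolError):
    """A patient cannot enter the analysis set; carries a machine-readable reason."""

    def __init__(self, reason: str, message: str = ""):
        self.reason = reason
        super().__init__(message or reason)


class ConfigError(HemoqolError, ValueError):
    """An infeasible or inconsistent configuration (e.g. LVET >= beat interval)."""


class ConvergenceError(HemoqolError):
    """A model fit failed to converge; carries optimizer diagnostics in args."""
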