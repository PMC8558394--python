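"""Exception hierarchy for crpdecomp."""


class CrpDecompError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CrpDecompError):
    """A generator or pipeline configuration value is missing or out of range."""


class CalibrationError(CrpDecompError):
    """The requested lognormal (mean, exceedance) pair has no valid solution."""


class InputError(CrpDecompError):
    """Invalid input to an analysis operation (wrong shape, missing group, ...)."""


class EmptyTableError(CrpDecompError):
    """A filtering step removed every row."""


class RankDeficiencyError(CrpDecompError):
    """A design (sub)matrix is rank deficient; carries the offending terms."""

    def __init__(self, message: str, terms=None):
        super().__init__(message)
        self.terms = list(terms) if terms is not None else []


class SeparationError(CrpDecompError):
    """Perfect separation in a logistic fit; a penalized fit is the usual fallback."""


class PhecodeParseError(CrpDecompError):
    """Malformed phecode map file; carries offending line numbers."""

    def __init__(self, message: str, lines=None):
        super().__init__(message)
        self.lines = list(lines) if lines is not None else []
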