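"""Exception hierarchy shared across the package."""


class NanosieveError(Exception):
    """Base class for all package errors."""


class ValidationError(NanosieveError, ValueError):
    """Caller supplied arguments that violate a documented precondition."""


class FormatError(NanosieveError):
    """A container file is structurally invalid (e.g. missing calibration)."""


class DegenerateSignalError(NanosieveError):
    """A window has zero MAD and cannot be robustly normalized."""


class InfeasibleModelError(NanosieveError):
    """Model parameters make the requested quantity undefined (e.g. TPR=0)."""
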