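"""Exception hierarchy shared across the package."""


class NichekitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NichekitError):
    """A file violates the expected on-disk format."""


class ValidationError(NichekitError):
    """An in-memory object violates a structural invariant."""


class ParameterError(NichekitError):
    """An argument is outside its admissible range."""


class InsufficientDataError(NichekitError):
    """Too few observations remain after filtering to compute a statistic."""

    def __init__(self, message: str, n_used: int = 0):
        super().__init__(message)
        self.n_used = n_used
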