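"""Exception hierarchy shared across the package."""


class PQXError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PQXError, ValueError):
    """A parameter lies outside its admissible region."""


class DomainError(PQXError, ValueError):
    """An argument (support point, order, ...) is outside the function domain."""


class MomentsIncompatibleError(PQXError, ValueError):
    """Sample moments are incompatible with the PQX family (e.g. under-dispersion)."""


class YWIncompatibleError(PQXError, ValueError):
    """Yule-Walker moment equations have no admissible solution for this series."""


class EMNumericalError(PQXError, RuntimeError):
    """An EM update became undefined (negative discriminant or boundary crossing)."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


class SeriesFormatError(PQXError, ValueError):
    """A count-series file failed to parse; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line
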