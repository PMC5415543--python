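"""Exception hierarchy shared across the package."""


class PhylothermError(Exception):
    """Base class for all package-specific errors."""


class NewickFormatError(PhylothermError):
    """Newick text could not be parsed; carries the character position if known."""

    def __init__(self, message, position=None):
        self.position = position
        if position is not None:
            message = f"{message} (near character {position})"
        super().__init__(message)


class ValidationError(PhylothermError):
    """Input violates a documented precondition (duplicate tips, unknown species, ...)."""


class DegenerateStructureError(PhylothermError):
    """A covariance/correlation matrix is not positive definite to tolerance."""


class UnidentifiableError(PhylothermError):
    """The data carry no information about the parameter (e.g. all-dead mortality tables)."""


class NoDoseResponseError(PhylothermError):
    """Probit slope numerically zero: no temperature-mortality relationship."""


class DesignError(PhylothermError):
    """Model design matrix is rank deficient or saturated."""

    def __init__(self, message, aliased=None):
        self.aliased = list(aliased) if aliased else []
        if self.aliased:
            message = f"{message}; aliased terms: {', '.join(self.aliased)}"
        super().__init__(message)


class UndefinedStatisticError(PhylothermError):
    """Statistic undefined on this input (e.g. Moran's I of a constant trait)."""
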