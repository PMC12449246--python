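"""Exception hierarchy for madvar-select."""


class MadvarError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(MadvarError):
    """The input data violates a precondition (shape, emptiness, finiteness...)."""


class InvalidParameterError(MadvarError):
    """A tuning parameter is outside its valid range."""


class NoIntersectionError(MadvarError):
    """The two weighted mixture densities do not cross between the component means.

    Carries the quadratic roots (if any) so callers can report where the
    densities actually cross.
    """

    def __init__(self, message: str, roots=()):
        super().__init__(message)
        self.roots = tuple(roots)


class FitError(MadvarError):
    """An iterative fit failed to produce a usable result."""
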