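"""Exception hierarchy shared across the package."""


class IllDeathError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(IllDeathError, ValueError):
    """Invalid user input (parameters, curves, configuration)."""


class DomainError(ValidationError):
    """A rate or curve was evaluated outside its age domain."""


class NumericError(IllDeathError, ArithmeticError):
    """An integrator or quadrature failed to produce a usable result."""


class SingularityError(NumericError):
    """The incidence formula hit its p -> 1 singularity."""


class AliasingError(ValidationError):
    """An oscillatory perturbation is unresolvable on the given grid."""


class ParseError(ValidationError):
    """A CSV or configuration file could not be parsed."""
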