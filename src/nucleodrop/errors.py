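"""Exception hierarchy shared across the package."""


class NucleodropError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(NucleodropError, ValueError):
    """A parameter is outside its documented domain."""


class ContractViolationError(NucleodropError, ValueError):
    """An input violates a structural precondition (e.g. open mesh where a
    closed one is required)."""


class InfeasibleConfigurationError(NucleodropError, ValueError):
    """The requested configuration is geometrically unattainable."""


class InvalidInputError(NucleodropError, ValueError):
    """Degenerate data that cannot be measured (e.g. collinear contour)."""
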