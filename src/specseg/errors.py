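"""Exception taxonomy shared across the package."""


class SpecsegError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SpecsegError, ValueError):
    """Invalid configuration object (dimensions, counts, rates)."""


class DomainError(SpecsegError, ValueError):
    """Value outside the mathematical domain of an operation."""


class DataError(SpecsegError, ValueError):
    """Input data violates a structural contract (missing structure, ...)."""


class ValidationError(SpecsegError, ValueError):
    """Input fails a validation rule (unnormalized probabilities, manifests)."""


class ShapeError(SpecsegError, ValueError):
    """Array shapes are incompatible."""


class FormatError(SpecsegError, ValueError):
    """Unrecognized or unsupported file format."""


class CapacityError(SpecsegError, ValueError):
    """Instance exceeds an exact-algorithm size bound."""


class CapabilityError(SpecsegError, RuntimeError):
    """Requested output requires a capability that was disabled."""


class NumericError(SpecsegError, ArithmeticError):
    """Non-finite values encountered during computation."""


class DegenerateSampleError(SpecsegError, ValueError):
    """A statistical test received a degenerate sample."""
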