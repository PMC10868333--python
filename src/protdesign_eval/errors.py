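"""Exception hierarchy shared across the package.

Every error raised on bad user input derives from :class:`ProtDesignError`
so callers (and the CLI) can catch one type.
"""


class ProtDesignError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ProtDesignError):
    """A file does not conform to its declared format."""


class ConfigError(ProtDesignError):
    """A configuration value is missing, unknown or invalid."""


class DimensionMismatchError(ProtDesignError):
    """Two inputs that must share a shape or index set do not."""


class InputTooSmallError(ProtDesignError):
    """Fewer observations than the operation requires."""


class DomainError(ProtDesignError):
    """A value lies outside the mathematical domain of a transform."""


class DegenerateInputError(ProtDesignError):
    """Input is formally valid but numerically degenerate (constant column,
    collinear coordinates, zero reference sum ...)."""


class InvariantViolationError(ProtDesignError):
    """A structured object violates one of its declared invariants."""
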