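"""Exception hierarchy shared across the package.

All errors are ``ValueError`` subclasses so callers who do not care about the
fine-grained class can catch a single built-in type.
"""


class ClonescreenError(ValueError):
    """Base class for all package-specific errors."""


class InvalidArgumentError(ClonescreenError):
    """An argument violates a documented precondition."""


class ValidationError(ClonescreenError):
    """An input table violates a structural invariant (names the offending row)."""


class EmptyInputError(ClonescreenError):
    """An operation received an empty table or set where data is required."""


class InsufficientDataError(ClonescreenError):
    """Too few observations to compute the requested statistic."""


class DegenerateInputError(ClonescreenError):
    """Input is structurally valid but carries no usable signal (e.g. rank 0)."""
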