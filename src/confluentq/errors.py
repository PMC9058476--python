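"""Exception hierarchy shared across the package."""


class ConfluentQError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ConfluentQError):
    """A delimited-text input does not have the expected layout."""


class ValidationError(ConfluentQError):
    """An input violates a structural precondition (duplicates, bad types...)."""


class DegenerateVarianceError(ConfluentQError):
    """A variable has zero spread, so it cannot be standardized or correlated."""


class MissingDataError(ConfluentQError):
    """A statistical operation was asked to run on a table with missing cells."""


class DegenerateGeometryError(ConfluentQError):
    """A molecular geometry does not determine the requested quantity."""


class DegenerateEigenvalueError(ConfluentQError):
    """A principal component is not unique (repeated eigenvalue)."""
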