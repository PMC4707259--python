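"""Exception types shared across the package."""


class RootznError(Exception):
    """Base class for all package-specific errors."""


class DomainViolationError(RootznError):
    """A mathematical precondition was violated (e.g. non-positive RSA)."""


class DegenerateSeriesError(RootznError):
    """A series cannot identify the three curve parameters."""


class UndefinedAttributionError(RootznError):
    """Attribution requested between groups with identical uptake."""


class SchemaError(RootznError):
    """A table does not conform to the tidy CSV schema."""


class PreconditionError(RootznError):
    """Experiment metadata invalidates the requested computation."""
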