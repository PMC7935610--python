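"""Exception hierarchy shared across the package."""


class CascadeflowError(Exception):
    """Base class for all package-specific errors."""


class LoadError(CascadeflowError):
    """Raised when an event file cannot be ingested."""


class FilterError(CascadeflowError):
    """Raised for malformed filter expressions or unknown columns."""


class ParameterError(CascadeflowError, ValueError):
    """Raised for invalid numeric parameters (bin widths, penalties, ...)."""


class SpecError(CascadeflowError):
    """Raised when a plot specification violates a cardinality rule."""


class ConsistencyError(CascadeflowError):
    """Raised when an internal invariant is violated (e.g. an event-free cascade)."""
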