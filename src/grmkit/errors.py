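"""Exception types shared across the package."""

from .model import InvalidParameterError  # noqa: F401  (re-export)


class SchemaError(ValueError):
    """Input table does not match the expected layout or value ranges."""


class DegenerateItemError(ValueError):
    """An item has too few observed categories to be calibrated."""


class InsufficientDataError(ValueError):
    """Too few observations to compute the requested statistic."""


class ConfigurationError(ValueError):
    """Invalid analysis configuration."""


class UndefinedReliabilityError(ValueError):
    """Subject separation is undefined (no variance in person estimates)."""
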