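"""Exception hierarchy shared across the package."""


class SepsisNetError(Exception):
    """Base class for all package errors."""


class SchemaError(SepsisNetError):
    """A table or configuration does not match the declared feature schema."""


class ValidationError(SepsisNetError):
    """A data value violates an invariant (bad label, non-numeric cell, ...)."""


class ConfigError(SepsisNetError):
    """An unknown or out-of-range configuration key."""


class ImputationError(SepsisNetError):
    """A column cannot be imputed (e.g. no observed values at all)."""


class EncodingError(SepsisNetError):
    """A categorical value outside the declared category order (strict mode)."""
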