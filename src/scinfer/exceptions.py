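"""Exception hierarchy shared across the package."""


class ScinferError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ScinferError, ValueError):
    """A required column or field is missing from an input table."""


class TableParseError(ScinferError, ValueError):
    """A cell could not be parsed; the message carries the offending line numbers."""


class ParameterError(ScinferError, ValueError):
    """An argument is outside its documented domain."""


class DataError(ScinferError, ValueError):
    """Input data violate a contract (non-finite values, no events, collinearity...)."""
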