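"""Exception hierarchy shared across the package."""


class ResistexError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ResistexError):
    """A delimited-text file does not have the expected header/columns."""


class ValidationError(ResistexError, ValueError):
    """Values violate a domain invariant (ranges, shapes, missingness)."""


class FilterError(ResistexError, KeyError):
    """A metadata filter references an unknown field."""
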