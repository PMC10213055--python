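"""Typed exceptions raised across the package.

Every malformed input raises one of these; nothing is silently coerced.
"""


class TilspatialError(Exception):
    """Base class for all package errors."""


class SchemaError(TilspatialError):
    """A required column or key is missing from an input table."""


class ParseError(TilspatialError):
    """A value could not be parsed into its declared type/domain."""


class ValidationError(TilspatialError):
    """A parsed value violates a data-model invariant."""


class ContractError(TilspatialError):
    """An operation was called with arguments outside its contract."""


class UndefinedResultError(TilspatialError):
    """The requested quantity is undefined for this input (e.g. empty field)."""
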