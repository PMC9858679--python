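"""Exception hierarchy shared across the package."""


class GenechainError(Exception):
    """Base class for all package errors."""


class SchemaError(GenechainError):
    """A table violates the column registry (missing targets, bad headers...)."""


class CellError(GenechainError):
    """A cell-level parse failure; carries (row, column) locations."""

    def __init__(self, message: str, locations=None):
        super().__init__(message)
        self.locations = list(locations or [])


class EncodingError(GenechainError):
    """A category string has no registered integer code."""

    def __init__(self, column: str, value):
        super().__init__(f"no encoding for value {value!r} in column {column!r}")
        self.column = column
        self.value = value


class DataError(GenechainError):
    """Semantically invalid data (empty class, shape mismatch, ...)."""


class ConfigError(GenechainError):
    """Invalid user-supplied configuration."""
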