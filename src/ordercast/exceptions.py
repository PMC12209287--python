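"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`OrdercastError`, so callers (and the CLI) can distinguish data
problems from programming errors.
"""


class OrdercastError(Exception):
    """Base class for all ordercast errors."""


class SchemaError(OrdercastError):
    """A CSV file does not conform to the judgment-record schema."""


class RecordParseError(OrdercastError):
    """A single cell could not be parsed; carries row index and field name."""

    def __init__(self, row: int, field: str, message: str):
        self.row = row
        self.field = field
        super().__init__(f"row {row}, field {field!r}: {message}")


class RecordValidationError(OrdercastError):
    """A parsed record violates a schema invariant."""


class NoModellableCasesError(OrdercastError):
    """Filtering left no accepted entire/partial cases to model."""


class FuzzyConfigError(OrdercastError):
    """The fuzzy rule registry or linguistic variables are inconsistent."""


class DomainError(OrdercastError):
    """A numeric argument lies outside its documented domain."""
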