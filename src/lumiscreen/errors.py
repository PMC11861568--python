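"""Exception hierarchy shared by all pipeline stages.

Exit-code mapping used by the CLI: :class:`ValidationError` (and
subclasses) exit with status 2, :class:`DegenerateDataError` with
status 3. Anything else is a bug and propagates.
"""


class LumiscreenError(Exception):
    """Base class for all package errors."""


class ValidationError(LumiscreenError):
    """Invalid inputs: bad schemas, out-of-range values, broken references."""


class SchemaError(ValidationError):
    """A required column or field is missing or malformed."""


class CapacityError(ValidationError):
    """A plate layout cannot hold the requested number of test wells."""


class ParseError(ValidationError):
    """A text input file could not be parsed; carries a line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class DegenerateDataError(LumiscreenError):
    """Statistically degenerate input (e.g. zero variance, too few controls)."""
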