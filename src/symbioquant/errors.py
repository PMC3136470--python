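"""Exception types shared across the pipeline."""


class SymbioquantError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(SymbioquantError):
    """A table is missing required columns or has an unusable header."""


class ParseError(SymbioquantError):
    """A row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(SymbioquantError):
    """Input violates a semantic contract (duplicates, bad vocabulary, ...)."""
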