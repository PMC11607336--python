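"""Exception hierarchy."""


class NotemiaError(Exception):
    """Base class for package errors."""


class ValidationError(NotemiaError, ValueError):
    """Invalid data (duplicate ids, ragged matrices, out-of-range values)."""


class ParseError(NotemiaError, ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ConfigError(NotemiaError, ValueError):
    """Unknown or inconsistent configuration keys."""


class ProtocolError(NotemiaError, RuntimeError):
    """The attack protocol cannot proceed (e.g. a single-class fold)."""


class GenerationError(NotemiaError, RuntimeError):
    """A generation backend failed; retriable."""
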