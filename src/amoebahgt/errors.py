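"""Exception hierarchy.

Argument errors map to CLI exit code 2, data/parse/generation errors to 3.
"""


class AmoebaHgtError(Exception):
    """Base class for all package errors."""


class ArgumentError(AmoebaHgtError, ValueError):
    """A caller-supplied argument violates a precondition."""


class ConfigError(AmoebaHgtError):
    """Invalid configuration (unknown matrix name, unknown format, ...)."""


class DataError(AmoebaHgtError):
    """Inconsistent or incomplete input data (missing taxonomy entry, ...)."""


class ParseError(DataError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class GenerationError(AmoebaHgtError):
    """The synthetic-data generator could not satisfy its constraints."""
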