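"""Exception hierarchy shared across the package."""


class AsflowError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(AsflowError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateTableError(InvalidInputError):
    """A contingency table has a zero expected count; use the exact test instead."""


class Gff3ParseError(AsflowError, ValueError):
    """A GFF3 file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class SamParseError(AsflowError, ValueError):
    """A SAM record could not be interpreted."""


class ConfigurationError(AsflowError, ValueError):
    """A configuration value is out of range or inconsistent."""


class NormalizationError(AsflowError, ValueError):
    """Normalization is impossible (e.g. a sample with zero assigned reads)."""
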