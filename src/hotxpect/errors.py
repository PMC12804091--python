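"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the command line interface:
``ValidationError`` -> 2, ``DataError`` -> 3, ``ConfigError`` -> 4.
"""


class HotxpectError(Exception):
    """Base class for all package errors."""


class ValidationError(HotxpectError):
    """Malformed input: schema violations, bad records, bad alphabets."""


class SchemaError(ValidationError):
    """A required column is missing or duplicated."""


class RecordError(ValidationError):
    """A single record could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class FrameError(ValidationError):
    """A coding sequence whose length is not 3L + 2."""


class AlphabetError(ValidationError):
    """A sequence containing characters outside A/C/G/T."""


class DataError(HotxpectError):
    """Inputs are well-formed but unusable for the requested computation."""


class ReferenceMismatchError(DataError):
    """A variant's reference allele disagrees with the reference sequence."""


class EmptyInputError(DataError):
    """An operation received an empty collection it cannot act on."""


class DegenerateModelError(DataError):
    """A model quantity needed for normalization is identically zero."""


class ConfigError(HotxpectError):
    """An invalid run or simulation configuration."""
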