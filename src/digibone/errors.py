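"""Exception hierarchy mapped to CLI exit codes.

Exit codes: 0 success, 2 schema/config error, 3 data error, 4 numerical error.
"""


class DigiboneError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SchemaError(DigiboneError):
    """A file or config does not match its documented schema."""

    exit_code = 2


class ConfigError(DigiboneError):
    """An invalid or inconsistent configuration value."""

    exit_code = 2


class DataError(DigiboneError):
    """Input data violates a contract (mixed sexes, missing masks, ...)."""

    exit_code = 3


class InvalidInputError(DigiboneError):
    """A function argument is outside its domain."""

    exit_code = 3


class NumericalError(DigiboneError):
    """A statistic is undefined for the given input (e.g. zero variance)."""

    exit_code = 4


class EmptySegmentError(DataError):
    """A segment mask is empty where a non-empty mask is required."""
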