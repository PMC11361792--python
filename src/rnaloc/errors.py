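"""Exception hierarchy.

CLI exit-code mapping: UsageError-like problems exit 2 (click handles those),
DataError subclasses exit 3, EnvironmentToolError exits 4.
"""


class RnalocError(Exception):
    """Base class for all package errors."""


class DataError(RnalocError):
    """Malformed or inconsistent user data (exit code 3)."""


class MalformedRecordError(DataError):
    """A sequence record violates the record contract (empty sequence, duplicate id, ...)."""


class StructureParseError(DataError):
    """A dot-bracket string cannot be parsed (unbalanced brackets, bad characters)."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class StructureMismatchError(DataError):
    """Structure and sequence lengths disagree for a record."""


class ConfigError(RnalocError):
    """Invalid configuration or incompatible tensor dimensions."""


class EnvironmentToolError(RnalocError):
    """A required external executable is missing or unusable (exit code 4)."""
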