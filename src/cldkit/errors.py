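"""Exception types shared across the toolkit."""

from __future__ import annotations


class CldkitError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(CldkitError):
    """A configuration value is invalid; the message names the offending field."""


class ParameterError(CldkitError):
    """A runtime parameter is outside its documented range."""


class ParseError(CldkitError):
    """A file could not be parsed.

    Parameters
    ----------
    message : str
        Human-readable description.
    line : int, optional
        1-based line number of the offending line, when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class FormatError(CldkitError):
    """An input object violates its format contract (e.g. a lengthless tree)."""


class MissingIdError(CldkitError, KeyError):
    """A referenced identifier (sequence, anchor, node, annotation) is absent."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the plain message
        return Exception.__str__(self)


class ResidueSpecError(CldkitError):
    """A key-residue specification does not match the reference sequence."""


class ConsistencyError(CldkitError):
    """Mutually inconsistent inputs (e.g. one member under two representatives)."""


class EmptyInputError(CldkitError):
    """An operation received an empty collection where members are required."""
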