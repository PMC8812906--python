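"""Exception hierarchy for fusiontriage.

Schema errors describe a file whose shape is wrong (missing columns or
headers); row parse errors describe a single bad data row and carry its
1-based line number; validation errors describe a value that violates a
domain invariant (bad strand, unknown SV class, inverted interval).
"""

from __future__ import annotations


class FusionTriageError(Exception):
    """Base class for all package errors."""


class ValidationError(FusionTriageError):
    """A field value violates a domain invariant."""


class SchemaError(FusionTriageError):
    """A table is missing required columns or headers."""


class RowParseError(FusionTriageError):
    """A single data row could not be parsed.

    Parameters
    ----------
    message : str
    line_no : int
        1-based line number within the source file, including any header.
    """

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


class AmbiguityError(RowParseError):
    """A fusion token cannot be split unambiguously into two gene symbols."""
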