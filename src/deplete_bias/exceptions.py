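"""Exception hierarchy.

All input problems raise :class:`ValidationError` (or a subclass), which the
CLI maps to exit code 2; genuine I/O failures propagate as ``OSError`` and map
to exit code 3.
"""

from __future__ import annotations


class DepleteBiasError(Exception):
    """Base class for all package errors."""


class ValidationError(DepleteBiasError):
    """Invalid input data or configuration."""


class ParseError(ValidationError):
    """Malformed input file; carries the path and 1-based line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class EmptyProfileError(ValidationError):
    """No abundance mass left after filtering/renormalization."""


class NormalizationError(ValidationError):
    """A profile that must sum to 100% does not."""
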