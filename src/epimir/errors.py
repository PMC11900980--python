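"""Exception hierarchy.

All parse errors carry file and row context so a bad input line can be
located without re-running under a debugger.
"""

from __future__ import annotations


class EpimirError(Exception):
    """Base class for all package errors."""


class ValidationError(EpimirError, ValueError):
    """An input value violates a documented contract."""


class ParameterError(EpimirError, ValueError):
    """A tunable parameter is outside its admissible range."""


class TableError(ValidationError):
    """A delimited-text table could not be parsed.

    Parameters
    ----------
    message : str
    path : str, optional
        Source file.
    row : int, optional
        1-based data-row number (header excluded).
    """

    def __init__(self, message: str, path=None, row=None):
        ctx = []
        if path is not None:
            ctx.append(f"file={path}")
        if row is not None:
            ctx.append(f"row={row}")
        if ctx:
            message = f"{message} ({', '.join(ctx)})"
        super().__init__(message)
        self.path = path
        self.row = row


class CatalogError(ValidationError):
    """The regulator catalog is internally inconsistent."""
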