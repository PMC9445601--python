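"""Exception hierarchy used across the package.

All errors raised for bad user input derive from :class:`InvalidInputError`
(itself a ``ValueError``) so callers can catch one type at the boundary.
"""


class FoliarError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(FoliarError, ValueError):
    """An input violates a documented precondition."""


class InsufficientDataError(InvalidInputError):
    """Too few observations for the requested fit (minimum is 3)."""


class DegenerateInputError(InvalidInputError):
    """Input with zero variance (or otherwise degenerate geometry)."""


class UndefinedSlopeSignError(DegenerateInputError):
    """SMA slope sign is undefined because the correlation is exactly zero."""


class FormatError(InvalidInputError):
    """A file does not conform to the documented table format."""
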