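"""Exception hierarchy shared across the package.

Every error raised by mdums derives from :class:`MdumsError`, so callers
(and the CLI) can catch the whole family with one clause.
"""


class MdumsError(Exception):
    """Base class for all mdums errors."""


class ValidationError(MdumsError, ValueError):
    """An input value violates a documented invariant (range, shape, symbol)."""


class UnitsError(ValidationError):
    """A matrix is in the wrong units for the requested operation."""


class InsufficientDataError(MdumsError):
    """Too few observations to compute the requested statistic."""


class AlignmentError(ValidationError):
    """Gapped rows are inconsistent (unequal lengths, duplicate ids, ...)."""


class CoordinateError(ValidationError):
    """A protein/domain coordinate does not match the annotated sequence."""


class ParseError(MdumsError, ValueError):
    """A text input could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
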