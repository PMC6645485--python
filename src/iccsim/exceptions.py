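"""Exception types raised by iccsim.

All inherit from :class:`ValueError` so callers that do not care about the
distinction can catch a single base class.
"""


class InvalidInputError(ValueError):
    """The score matrix (or parameter set) violates a structural requirement,
    e.g. fewer than two subjects or measurements, missing or non-numeric cells."""


class ParseError(InvalidInputError):
    """A matrix file could not be parsed into a complete numeric rectangle.

    Carries the offending row/column (1-based) when known.
    """

    def __init__(self, message: str, row: int | None = None, column: int | None = None):
        if row is not None:
            loc = f" (row {row}" + (f", column {column}" if column is not None else "") + ")"
            message += loc
        super().__init__(message)
        self.row = row
        self.column = column


class DegenerateInputError(ValueError):
    """A quantity is undefined for this input, e.g. an ICC denominator of zero
    for a constant matrix, or an F-test with MSE = 0."""


class InsufficientSampleError(ValueError):
    """Too few values to form the requested empirical central range."""


class GridResolutionError(ValueError):
    """The population-ICC grid is too coarse to bracket the requested value."""
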