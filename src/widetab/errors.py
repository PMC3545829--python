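"""Exception hierarchy.

Everything raised on purpose by widetab derives from :class:`WidetabError`,
so callers (and the CLI exit-code mapping) can catch one base class.
"""


class WidetabError(Exception):
    """Base class for all errors raised by widetab."""


# --- catalog (GroupFilterFormat) -------------------------------------------

class GffError(WidetabError):
    """Base class for catalog definition errors."""


class EmptyCatalogError(GffError):
    """The catalog text is blank."""


class GffSyntaxError(GffError):
    """Malformed catalog text; carries 1-based line and column."""

    def __init__(self, message: str, line: int, column: int):
        super().__init__(f"{message} (line {line}, column {column})")
        self.line = line
        self.column = column


class DuplicateGroupNameError(GffSyntaxError):
    pass


class DuplicateItemCodeError(GffSyntaxError):
    pass


class NonNumericValueError(GffSyntaxError):
    pass


# --- record I/O -------------------------------------------------------------

class BadDateError(WidetabError):
    """A date field could not be parsed as a valid calendar date."""


class MissingColumnError(WidetabError):
    """A required column is absent from an input row."""


class NonScalarCellError(WidetabError):
    """Scalar output was requested but a cell still holds a bag of events."""


# --- date arithmetic ---------------------------------------------------------

class DateOverflowError(WidetabError):
    """Date arithmetic left the supported proleptic-Gregorian range."""


class NegativeAgeError(WidetabError):
    """Birth date lies after the reference date."""


# --- transformation ----------------------------------------------------------

class ValueIndexOutOfRangeError(WidetabError):
    """An item defines fewer attached values than the requested index."""


class MissingValuesError(WidetabError):
    """An item carries no attached values but a numeric join was requested."""


class NonNumericCellError(WidetabError):
    """SUM/MAX/MIN requested without a numeric value source."""


class EmptyCellError(WidetabError):
    """An operation that needs at least one event got an empty cell."""


# --- engine ------------------------------------------------------------------

class MapError(WidetabError):
    """Wraps an exception raised while mapping a record; names the shard."""


class ReduceError(WidetabError):
    """Wraps an exception raised while reducing a key's bag."""


# --- parameters / regression -------------------------------------------------

class InvalidParamsError(WidetabError):
    """A parameter violates its documented domain."""


class DegenerateDesignError(WidetabError):
    """Regression requires at least two distinct x values."""


class NonPositiveValueError(WidetabError):
    """Power-law fitting requires strictly positive observations."""
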