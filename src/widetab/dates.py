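"""Calendar-date functions for event-log processing.

Three primitives cover the date handling that long-to-wide cohort
construction needs: signed day intervals between events, date shifting by
a day count, and extraction of consecutive daily administration runs
(e.g. a course of a drug given every day from admission).  All arithmetic
is integer arithmetic on proleptic-Gregorian day ordinals, so it is exact
and independently checkable.
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable, Sequence

from .errors import DateOverflowError, InvalidParamsError, NegativeAgeError
from .records_io import EventRecord

__all__ = [
    "get_day_span",
    "add_day_span",
    "pickup_sequence_values",
    "age_in_years",
]


def get_day_span(d1: dt.date, d2: dt.date) -> int:
    """Signed whole-day interval from *d1* to *d2* (``d2 - d1``)."""
    return d2.toordinal() - d1.toordinal()


def add_day_span(d: dt.date, n: int) -> dt.date:
    """The date *n* days after *d*; *n* may be negative.

    ``get_day_span(d, add_day_span(d, n)) == n`` for every in-range result.
    """
    try:
        return dt.date.fromordinal(d.toordinal() + int(n))
    except (ValueError, OverflowError) as exc:
        raise DateOverflowError(
            f"{d.isoformat()} {n:+d} days leaves the supported calendar range"
        ) from exc


def pickup_sequence_values(
    events: Iterable[EventRecord],
    start: dt.date,
    period_days: int,
    *,
    max_gap: int = 0,
) -> list[EventRecord]:
    """Events belonging to the consecutive daily run anchored at *start*.

    An event survives iff its date lies within ``[start, start+period_days-1]``
    and every calendar day from *start* up to the event's day is covered by
    at least one input event — i.e. the maximal gap-free daily run anchored
    at the start date, truncated at the period bound.  If no event falls on
    the start date itself the result is empty.  The rule operates on days:
    all events of an included day are retained together.

    ``max_gap`` relaxes "gap-free" to tolerate up to that many missing days
    between covered days (default 0, the strict reading); the run is still
    anchored at a covered start date.
    """
    if period_days < 1:
        raise InvalidParamsError(f"period_days must be ≥ 1, got {period_days}")
    if max_gap < 0:
        raise InvalidParamsError(f"max_gap must be ≥ 0, got {max_gap}")
    events = list(events)
    offsets = sorted({
        get_day_span(start, e.event_date)
        for e in events
        if 0 <= get_day_span(start, e.event_date) < period_days
    })
    if not offsets or offsets[0] != 0:
        return []
    cutoff = 0
    for off in offsets[1:]:
        if off - cutoff <= max_gap + 1:
            cutoff = off
        else:
            break
    return [
        e for e in events
        if 0 <= get_day_span(start, e.event_date) <= cutoff
    ]


def age_in_years(birth: dt.date, at: dt.date) -> int:
    """Completed calendar years between *birth* and *at*.

    The year count decrements when the anniversary has not yet occurred in
    the year of *at*.  A Feb 29 birthday's anniversary falls on Mar 1 in
    non-leap years.
    """
    if birth > at:
        raise NegativeAgeError(
            f"birth {birth.isoformat()} is after reference {at.isoformat()}"
        )
    years = at.year - birth.year
    month, day = birth.month, birth.day
    if month == 2 and day == 29 and not _is_leap(at.year):
        month, day = 3, 1
    if (at.month, at.day) < (month, day):
        years -= 1
    return years


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)
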