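"""Long-to-wide transformation primitives.

The pivot proceeds in separable steps so both the bag view and the scalar
view stay inspectable:

* :func:`exists_filter` — drop events whose code the catalog does not
  define (map-phase volume reduction);
* :func:`inner_group` — collect one key's events into per-group cells of a
  wide row (the pivot proper);
* :func:`value_join` — attach the catalog's numeric values (dose, price,
  ...) to matched events for numeric processing;
* :func:`aggregate` — collapse a cell's bag to a scalar with the familiar
  COUNT / SUM / MAX / MIN reductions, plus first/last event date.

Helpers for the two canonical epidemiological derived variables — the
first-to-last administration interval and exposure within a window after
an index date — sit alongside.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from .dates import get_day_span
from .errors import (
    EmptyCellError,
    InvalidParamsError,
    MissingValuesError,
    NonNumericCellError,
    ValueIndexOutOfRangeError,
)
from .gff import GroupCatalog
from .records_io import EventRecord, WideRow

__all__ = [
    "AGG_OPS",
    "AggEntry",
    "AggregationSpec",
    "parse_aggspec",
    "exists_filter",
    "inner_group",
    "value_join",
    "aggregate",
    "first_last_interval",
    "exposure_within_window",
]

AGG_OPS = ("COUNT", "SUM", "MAX", "MIN", "FIRST_DATE", "LAST_DATE", "BAG")

_NEEDS_SOURCE = {"SUM", "MAX", "MIN"}


@dataclass(frozen=True)
class AggEntry:
    """Aggregation for one group: an operation plus its value source.

    ``source`` is ``("value", k)`` for the catalog-joined value at index k,
    ``("quantity",)`` for the event's own quantity field, or None for
    operations that need no numbers (COUNT, FIRST_DATE, LAST_DATE, BAG).
    """

    op: str
    source: tuple | None = None

    def __post_init__(self):
        if self.op not in AGG_OPS:
            raise InvalidParamsError(f"unknown aggregation {self.op!r}")
        if self.op in _NEEDS_SOURCE and self.source is None:
            raise InvalidParamsError(
                f"{self.op} needs a value source (value index or quantity)"
            )
        if self.source is not None and self.source[0] not in ("value", "quantity"):
            raise InvalidParamsError(f"unknown value source {self.source!r}")


AggregationSpec = dict  # group name -> AggEntry


def parse_aggspec(text: str, catalog: GroupCatalog) -> AggregationSpec:
    """Parse ``"abx=COUNT,dose=SUM@0,units=SUM@qty"`` into an AggregationSpec.

    ``OP@k`` takes the joined value at index ``k``; ``OP@qty`` takes the
    event quantity.  Groups not mentioned default to COUNT, so every
    catalog group ends up with exactly one aggregation.
    """
    spec: AggregationSpec = {}
    if text.strip():
        for part in text.split(","):
            part = part.strip()
            if not part:
                continue
            if "=" not in part:
                raise InvalidParamsError(f"bad aggregation clause {part!r}")
            group, op_text = (s.strip() for s in part.split("=", 1))
            if group not in catalog.group_names:
                raise InvalidParamsError(f"unknown group {group!r} in aggregation")
            if group in spec:
                raise InvalidParamsError(f"group {group!r} aggregated twice")
            source = None
            if "@" in op_text:
                op, src = (s.strip() for s in op_text.split("@", 1))
                if src.lower() in ("qty", "quantity"):
                    source = ("quantity",)
                else:
                    try:
                        source = ("value", int(src))
                    except ValueError:
                        raise InvalidParamsError(
                            f"bad value source {src!r} for group {group!r}"
                        ) from None
            else:
                op = op_text
            spec[group] = AggEntry(op.upper(), source)
    for name in catalog.group_names:
        spec.setdefault(name, AggEntry("COUNT"))
    return spec


class exists_filter:
    """Stream filter keeping only events whose code the catalog defines.

    Iterable; relative order is preserved and :attr:`n_dropped` counts the
    excluded records (complete once the stream is exhausted).
    """

    def __init__(self, records: Iterable[EventRecord], catalog: GroupCatalog):
        self._records = iter(records)
        self._catalog = catalog
        self.n_dropped = 0
        self.n_kept = 0

    def __iter__(self) -> Iterator[EventRecord]:
        return self

    def __next__(self) -> EventRecord:
        for record in self._records:
            if record.code in self._catalog:
                self.n_kept += 1
                return record
            self.n_dropped += 1
        raise StopIteration


def inner_group(
    key: tuple[str, ...],
    records: Iterable[EventRecord],
    catalog: GroupCatalog,
) -> WideRow:
    """Pivot one key's event bag into a wide row of per-group cells.

    Every record lands in the cell of each group containing its code (a
    code in two groups contributes to both); groups with no match get an
    empty bag.  Cell contents are ordered by (date, code, input order) so
    downstream output is reproducible regardless of shuffle order.
    """
    cells: dict[str, list[EventRecord]] = {name: [] for name in catalog.group_names}
    ordered = sorted(
        enumerate(records),
        key=lambda ir: (ir[1].event_date, ir[1].code, ir[0]),
    )
    for _, record in ordered:
        for group_name, _values in catalog.lookup(record.code):
            cells[group_name].append(record)
    return WideRow(key=tuple(key), cells=cells)


def value_join(
    cell: Sequence[EventRecord],
    catalog: GroupCatalog,
    group: str,
    value_index: int,
) -> list[tuple[EventRecord, float]]:
    """Pair each event in a cell with its item's value at *value_index*.

    The value tuple is the one the catalog attaches to the event's code
    within *group*.  Items with no values raise
    :class:`MissingValuesError`; too-short value tuples raise
    :class:`ValueIndexOutOfRangeError`.
    """
    out = []
    for event in cell:
        values = catalog.values_for(group, event.code)
        if not values:
            raise MissingValuesError(
                f"item {event.code!r} in group {group!r} has no attached values"
            )
        if not 0 <= value_index < len(values):
            raise ValueIndexOutOfRangeError(
                f"value index {value_index} out of range for item "
                f"{event.code!r} in group {group!r} ({len(values)} values)"
            )
        out.append((event, values[value_index]))
    return out


def _numbers(cell: Sequence[EventRecord], catalog: GroupCatalog, group: str,
             entry: AggEntry) -> list[float]:
    if entry.source is None:
        raise NonNumericCellError(
            f"{entry.op} on group {group!r} has no numeric value source"
        )
    if entry.source[0] == "value":
        return [v for _, v in value_join(cell, catalog, group, entry.source[1])]
    nums = []
    for event in cell:
        if event.quantity is None:
            raise NonNumericCellError(
                f"event {event.code!r} on {event.event_date} has no quantity"
            )
        nums.append(event.quantity)
    return nums


def aggregate(cell: Sequence[EventRecord], entry: AggEntry,
              catalog: GroupCatalog, group: str):
    """Collapse a cell's bag per its aggregation entry.

    Empty bags yield COUNT 0 and SUM 0; MAX/MIN/FIRST_DATE/LAST_DATE yield
    an empty cell (None).  BAG passes the bag through unchanged.
    """
    cell = list(cell)
    if entry.op == "COUNT":
        return len(cell)
    if entry.op == "BAG":
        return cell
    if entry.op == "FIRST_DATE":
        return min((e.event_date for e in cell), default=None)
    if entry.op == "LAST_DATE":
        return max((e.event_date for e in cell), default=None)
    if not cell:
        return 0.0 if entry.op == "SUM" else None
    nums = _numbers(cell, catalog, group, entry)
    if entry.op == "SUM":
        return float(sum(nums))
    return float(max(nums)) if entry.op == "MAX" else float(min(nums))


def first_last_interval(cell: Sequence[EventRecord]) -> int:
    """Day span between the earliest and latest event in a cell.

    A single event gives 0.  Empty cells raise :class:`EmptyCellError` —
    there is no interval to speak of.
    """
    dates = [e.event_date for e in cell]
    if not dates:
        raise EmptyCellError("cannot take first-last interval of an empty cell")
    return get_day_span(min(dates), max(dates))


def exposure_within_window(
    cell: Sequence[EventRecord],
    index_date: dt.date,
    window_days: int,
    *,
    include_day0: bool = True,
) -> bool:
    """Whether any event falls within *window_days* after *index_date*.

    True iff some event date d satisfies ``0 ≤ d − index_date ≤
    window_days`` (inclusive at both ends; ``include_day0=False`` shifts
    the lower bound to 1, for the reading "after, not on, the index day").
    """
    if window_days < 0:
        raise InvalidParamsError(f"window_days must be ≥ 0, got {window_days}")
    low = 0 if include_day0 else 1
    return any(
        low <= get_day_span(index_date, e.event_date) <= window_days
        for e in cell
    )
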