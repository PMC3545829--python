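"""Delimited-text I/O for event logs, discharge summaries and wide tables.

The default dialect is tab-separated UTF-8 text without quoting, with an
optional header row and positional fallback — the convention of the
dataflow systems this tool's pipeline structure mirrors.  Dates travel as
ISO ``YYYY-MM-DD`` (or compact ``YYYYMMDD``) and are held internally as
:class:`datetime.date`, whose proleptic-Gregorian day ordinals make all
interval arithmetic exact integer arithmetic.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from itertools import chain
from typing import IO, Iterable, Iterator, Mapping, Sequence

from .errors import BadDateError, MissingColumnError, NonScalarCellError

__all__ = [
    "EventRecord",
    "SummaryRecord",
    "WideRow",
    "parse_date",
    "format_date",
    "RecordStream",
    "read_events",
    "read_summaries",
    "write_events",
    "write_summaries",
    "write_wide_table",
]

EVENT_COLUMNS = ("subject_id", "episode_id", "date", "code", "quantity")
SUMMARY_COLUMNS = (
    "subject_id",
    "episode_id",
    "admission_date",
    "discharge_date",
    "birth_date",
    "sex",
)


@dataclass(frozen=True, slots=True)
class EventRecord:
    """One long-format medical activity row."""

    subject_id: str
    episode_id: str | None
    event_date: dt.date
    code: str
    quantity: float | None = None

    def __reduce__(self):  # keeps worker IPC cheap
        return (self.__class__, (self.subject_id, self.episode_id,
                                 self.event_date, self.code, self.quantity))


@dataclass(frozen=True, slots=True)
class SummaryRecord:
    """One discharge-summary row (one admission episode)."""

    subject_id: str
    episode_id: str
    admission_date: dt.date
    discharge_date: dt.date
    birth_date: dt.date
    sex: str

    def __reduce__(self):
        return (self.__class__, (self.subject_id, self.episode_id,
                                 self.admission_date, self.discharge_date,
                                 self.birth_date, self.sex))


@dataclass(slots=True)
class WideRow:
    """One wide-table row: a grouping key plus named cells.

    Cells map column name to either an aggregated scalar or a bag of
    events (list), depending on the pipeline stage.
    """

    key: tuple[str, ...]
    cells: dict = field(default_factory=dict)


def parse_date(text: str) -> dt.date:
    """Parse ISO ``YYYY-MM-DD`` or compact ``YYYYMMDD``; reject all else."""
    s = text.strip()
    try:
        if len(s) == 10 and s[4] == "-" and s[7] == "-":
            return dt.date(int(s[:4]), int(s[5:7]), int(s[8:10]))
        if len(s) == 8 and s.isdigit():
            return dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
    except ValueError:
        pass
    raise BadDateError(f"unparseable date {text!r}")


def format_date(d: dt.date) -> str:
    return d.isoformat()


class RecordStream:
    """Lazy record iterator that counts malformed rows it skipped.

    In strict mode the first malformed row aborts with the underlying
    error; otherwise malformed rows are counted in :attr:`n_malformed`
    (fully known only once the stream is exhausted) and skipped.
    """

    def __init__(self, source: Iterator):
        self._source = source
        self.n_malformed = 0
        self.n_read = 0

    def __iter__(self):
        return self

    def __next__(self):
        return next(self._source)


def _open_maybe(source, mode: str) -> tuple[IO, bool]:
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode, encoding="utf-8", newline=""), True


def _split_lines(fh: IO, delimiter: str) -> Iterator[tuple[int, list[str]]]:
    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n").rstrip("\r")
        if not line:
            continue
        yield lineno, line.split(delimiter)


def _resolve_columns(
    first_fields: list[str], expected: Sequence[str], required: int
) -> tuple[dict[str, int] | None, bool]:
    """Header detection: a first row naming any expected column is a header.

    Returns (mapping or None for positional, first_row_is_header).
    """
    lowered = [f.strip().lower() for f in first_fields]
    if any(name in lowered for name in expected):
        mapping = {name: lowered.index(name) for name in expected if name in lowered}
        for name in expected[:required]:
            if name not in mapping:
                raise MissingColumnError(f"header lacks required column {name!r}")
        return mapping, True
    if len(first_fields) < required:
        raise MissingColumnError(
            f"row has {len(first_fields)} fields, need at least {required}"
        )
    return None, False


def _field(fields: list[str], mapping: Mapping[str, int] | None, name: str,
           position: int, lineno: int, required: bool) -> str | None:
    if mapping is not None:
        idx = mapping.get(name)
        if idx is None:
            return None
    else:
        idx = position
    if idx >= len(fields):
        if required:
            raise MissingColumnError(f"row {lineno}: missing column {name!r}")
        return None
    value = fields[idx].strip()
    if not value:
        if required:
            raise MissingColumnError(f"row {lineno}: empty required column {name!r}")
        return None
    return value


def read_events(source, *, delimiter: str = "\t", strict: bool = False) -> RecordStream:
    """Lazily read event records from a path or text stream.

    Columns, by header name or position: subject_id, episode_id, date,
    code, quantity (quantity optional).  Malformed rows raise in strict
    mode and are counted and skipped otherwise.
    """
    fh, close = _open_maybe(source, "r")

    def gen(stream: RecordStream):
        try:
            rows = _split_lines(fh, delimiter)
            first = next(rows, None)
            if first is None:
                return
            mapping, is_header = _resolve_columns(first[1], EVENT_COLUMNS, 4)
            pending = [] if is_header else [first]
            for lineno, fields in chain(pending, rows):
                stream.n_read += 1
                try:
                    subject = _field(fields, mapping, "subject_id", 0, lineno, True)
                    episode = _field(fields, mapping, "episode_id", 1, lineno, False)
                    date = parse_date(
                        _field(fields, mapping, "date", 2, lineno, True)
                    )
                    code = _field(fields, mapping, "code", 3, lineno, True)
                    qty_text = _field(fields, mapping, "quantity", 4, lineno, False)
                    qty = float(qty_text) if qty_text is not None else None
                except (BadDateError, MissingColumnError, ValueError) as exc:
                    if strict:
                        if isinstance(exc, ValueError) and not isinstance(
                            exc, (BadDateError, MissingColumnError)
                        ):
                            raise BadDateError(f"row {lineno}: {exc}") from exc
                        raise type(exc)(f"row {lineno}: {exc}") from exc
                    stream.n_malformed += 1
                    continue
                yield EventRecord(subject, episode, date, code, qty)
        finally:
            if close:
                fh.close()

    stream = RecordStream(iter(()))
    stream._source = gen(stream)
    return stream


def read_summaries(source, *, delimiter: str = "\t", strict: bool = False) -> RecordStream:
    """Lazily read discharge-summary records; validates date ordering.

    Rows violating admission ≤ discharge or birth ≤ admission are treated
    as malformed.
    """
    fh, close = _open_maybe(source, "r")

    def gen(stream: RecordStream):
        try:
            rows = _split_lines(fh, delimiter)
            first = next(rows, None)
            if first is None:
                return
            mapping, is_header = _resolve_columns(first[1], SUMMARY_COLUMNS, 6)
            pending = [] if is_header else [first]
            for lineno, fields in chain(pending, rows):
                stream.n_read += 1
                try:
                    rec = SummaryRecord(
                        _field(fields, mapping, "subject_id", 0, lineno, True),
                        _field(fields, mapping, "episode_id", 1, lineno, True),
                        parse_date(_field(fields, mapping, "admission_date", 2, lineno, True)),
                        parse_date(_field(fields, mapping, "discharge_date", 3, lineno, True)),
                        parse_date(_field(fields, mapping, "birth_date", 4, lineno, True)),
                        _field(fields, mapping, "sex", 5, lineno, True),
                    )
                    if rec.admission_date > rec.discharge_date:
                        raise BadDateError(
                            f"row {lineno}: admission after discharge"
                        )
                    if rec.birth_date > rec.admission_date:
                        raise BadDateError(f"row {lineno}: birth after admission")
                except (BadDateError, MissingColumnError) as exc:
                    if strict:
                        raise
                    stream.n_malformed += 1
                    continue
                yield rec
        finally:
            if close:
                fh.close()

    stream = RecordStream(iter(()))
    stream._source = gen(stream)
    return stream


def _format_quantity(q: float | None) -> str:
    if q is None:
        return ""
    f = float(q)
    return str(int(f)) if f.is_integer() else repr(f)


def write_events(records: Iterable[EventRecord], sink, *,
                 delimiter: str = "\t", header: bool = True) -> int:
    fh, close = _open_maybe(sink, "w")
    try:
        if header:
            fh.write(delimiter.join(EVENT_COLUMNS) + "\n")
        n = 0
        for r in records:
            fh.write(delimiter.join((
                r.subject_id,
                r.episode_id or "",
                format_date(r.event_date),
                r.code,
                _format_quantity(r.quantity),
            )) + "\n")
            n += 1
        return n
    finally:
        if close:
            fh.close()


def write_summaries(records: Iterable[SummaryRecord], sink, *,
                    delimiter: str = "\t", header: bool = True) -> int:
    fh, close = _open_maybe(sink, "w")
    try:
        if header:
            fh.write(delimiter.join(SUMMARY_COLUMNS) + "\n")
        n = 0
        for r in records:
            fh.write(delimiter.join((
                r.subject_id,
                r.episode_id,
                format_date(r.admission_date),
                format_date(r.discharge_date),
                format_date(r.birth_date),
                r.sex,
            )) + "\n")
            n += 1
        return n
    finally:
        if close:
            fh.close()


def render_cell(value, *, allow_bags: bool = False) -> str:
    """Render one wide-table cell deterministically.

    Empty cells (None or empty bag) become the empty string; integral
    floats drop the fraction; dates render ISO.  Bags are only rendered
    when explicitly allowed, as ``code@date`` entries joined by ``|``.
    """
    if value is None:
        return ""
    if isinstance(value, (list, tuple)):
        if not allow_bags:
            raise NonScalarCellError(
                "cell holds a bag of events but scalar output was requested"
            )
        return "|".join(
            f"{e.code}@{format_date(e.event_date)}" for e in value
        )
    if isinstance(value, dt.date):
        return format_date(value)
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return str(int(value)) if value.is_integer() else repr(value)
    return str(value)


def write_wide_table(rows: Iterable[WideRow], schema: Sequence[str], sink, *,
                     delimiter: str = "\t", allow_bags: bool = False) -> int:
    """Write wide rows under *schema* (key columns first), sorted by key.

    Returns the number of data rows written.  Missing cells render as the
    empty string, so output shape is fixed by the schema alone.
    """
    fh, close = _open_maybe(sink, "w")
    try:
        fh.write(delimiter.join(schema) + "\n")
        n = 0
        for row in sorted(rows, key=lambda r: r.key):
            arity = len(row.key)
            fields = list(row.key)
            for col in schema[arity:]:
                fields.append(render_cell(row.cells.get(col), allow_bags=allow_bags))
            fh.write(delimiter.join(fields) + "\n")
            n += 1
        return n
    finally:
        if close:
            fh.close()
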