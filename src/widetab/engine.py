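"""Local map→shuffle→reduce executor.

The engine gives the transformation functions the same phase structure a
distributed MapReduce cluster would — a map over input shards, a shuffle
grouping mapped pairs by key, and a reduce over each key's bag — while
guaranteeing that the output is byte-identical regardless of worker count
or input sharding.  Determinism comes from construction, not luck: shards
are processed in order, the shuffle preserves map-output order within each
key's bag, reduce runs over keys in sorted order, and output rows are
emitted in key order.

The parallel backend uses fork-based process pools.  Workers receive only
shard (or key-block) indices and inherit the input through the fork, so
inter-process traffic carries results only; there is no shared mutable
state and all communication flows through the shuffle.  ``workers=1`` is
the plain sequential reference path.
"""

from __future__ import annotations

import multiprocessing as mp
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .dates import age_in_years, pickup_sequence_values
from .errors import InvalidParamsError, MapError, ReduceError
from .gff import GroupCatalog
from .records_io import EventRecord, SummaryRecord, WideRow, write_wide_table
from .transform import AggregationSpec, aggregate, inner_group

__all__ = [
    "MapReduceJob",
    "TimingResult",
    "PickupSpec",
    "WideTable",
    "run_job",
    "run_pipeline",
]


@dataclass
class MapReduceJob:
    """A map function, a reduce function, and execution knobs.

    ``map_fn(record)`` returns an iterable of (key, value) pairs;
    ``reduce_fn(key, bag)`` returns an iterable of output rows.  Both must
    be pure with respect to the job — no hidden shared state — and
    picklable (module-level functions or partials) when ``workers > 1``.
    """

    map_fn: Callable
    reduce_fn: Callable
    workers: int = 1
    shard_size: int = 50_000

    def __post_init__(self):
        if self.workers < 1:
            raise InvalidParamsError(f"workers must be ≥ 1, got {self.workers}")
        if self.shard_size < 1:
            raise InvalidParamsError(
                f"shard_size must be ≥ 1, got {self.shard_size}"
            )


@dataclass(frozen=True)
class TimingResult:
    """One benchmark observation."""

    records: int
    workers: int
    repetition: int
    elapsed_seconds: float

    def __post_init__(self):
        if self.elapsed_seconds <= 0:
            raise InvalidParamsError("elapsed_seconds must be positive")


def _chunk(records: Iterable, size: int) -> list[list]:
    shards, shard = [], []
    for record in records:
        shard.append(record)
        if len(shard) >= size:
            shards.append(shard)
            shard = []
    if shard:
        shards.append(shard)
    return shards


def _map_shard(map_fn: Callable, shard_id: int, shard: list) -> list:
    out = []
    for record in shard:
        try:
            out.extend(map_fn(record))
        except Exception as exc:
            raise MapError(
                f"map failed on shard {shard_id}, record {record!r}: {exc}"
            ) from exc
    return out


def _reduce_block(reduce_fn: Callable, block: list) -> list:
    rows = []
    for key, bag in block:
        try:
            rows.extend(reduce_fn(key, bag))
        except Exception as exc:
            raise ReduceError(f"reduce failed on key {key!r}: {exc}") from exc
    return rows


# Fork-inherited task state: set in the parent immediately before the pool
# is created, visible to children through the fork, cleared afterwards.
_TASK_STATE: tuple | None = None


def _map_task(shard_id: int) -> list:
    map_fn, shards = _TASK_STATE
    return _map_shard(map_fn, shard_id, shards[shard_id])


def _reduce_task(block_id: int) -> list:
    reduce_fn, blocks = _TASK_STATE
    return _reduce_block(reduce_fn, blocks[block_id])


def _run_parallel(task: Callable, n_tasks: int, workers: int, state: tuple) -> list:
    global _TASK_STATE
    _TASK_STATE = state
    try:
        try:
            ctx = mp.get_context("fork")
        except ValueError:  # platform without fork: sequential fallback
            return [task(i) for i in range(n_tasks)]
        with ctx.Pool(processes=min(workers, n_tasks)) as pool:
            return pool.map(task, range(n_tasks))
    finally:
        _TASK_STATE = None


def run_job(
    records: Iterable,
    job: MapReduceJob,
    *,
    shards: Sequence[Sequence] | None = None,
    stats: dict | None = None,
) -> list:
    """Execute one map→shuffle→reduce pass and return the output rows.

    Every input record is mapped exactly once; all values sharing a key are
    presented to exactly one reduce invocation as one bag; rows come back
    sorted by key.  ``shards`` overrides the automatic equal-size sharding
    (used to demonstrate shard invariance).  When a dict is passed as
    ``stats`` it is filled with phase-level record counts.
    """
    if shards is None:
        shard_list = _chunk(records, job.shard_size)
    else:
        shard_list = [list(s) for s in shards]
    n_input = sum(len(s) for s in shard_list)

    # map phase
    if job.workers == 1 or len(shard_list) <= 1:
        mapped = [
            _map_shard(job.map_fn, i, shard)
            for i, shard in enumerate(shard_list)
        ]
    else:
        mapped = _run_parallel(
            _map_task, len(shard_list), job.workers, (job.map_fn, shard_list)
        )

    # shuffle: group by key, bag order = map-output order (deterministic
    # because shards are concatenated in order)
    groups: dict = {}
    n_mapped = 0
    for shard_out in mapped:
        for key, value in shard_out:
            groups.setdefault(key, []).append(value)
            n_mapped += 1
    grouped = sorted(groups.items())

    # reduce phase over contiguous key blocks; concatenation in block order
    # keeps global key order regardless of how many workers ran
    if job.workers == 1 or len(grouped) <= 1:
        rows = _reduce_block(job.reduce_fn, grouped)
    else:
        n_blocks = min(len(grouped), job.workers * 4)
        size, extra = divmod(len(grouped), n_blocks)
        blocks, at = [], 0
        for b in range(n_blocks):
            step = size + (1 if b < extra else 0)
            blocks.append(grouped[at:at + step])
            at += step
        parts = _run_parallel(
            _reduce_task, len(blocks), job.workers, (job.reduce_fn, blocks)
        )
        rows = [row for part in parts for row in part]

    if stats is not None:
        stats.update(
            n_input=n_input,
            n_mapped=n_mapped,
            n_keys=len(grouped),
            reduce_input_total=sum(len(bag) for _, bag in grouped),
            n_rows=len(rows),
        )
    return rows


# --------------------------------------------------------------------------
# The full long-to-wide pipeline
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PickupSpec:
    """Restrict a group's cell to the consecutive daily run anchored at the
    key's admission date, truncated at ``period_days``."""

    period_days: int
    max_gap: int = 0


SUMMARY_COLUMNS = ("admission_date", "discharge_date", "sex", "age")


@dataclass
class WideTable:
    """A materialized wide table: ordered column schema plus key-sorted rows."""

    schema: tuple[str, ...]
    rows: list[WideRow]

    def to_tsv(self, sink=None, *, delimiter: str = "\t",
               allow_bags: bool = False) -> str | int:
        """Write as delimited text; returns the text when *sink* is None."""
        if sink is None:
            import io

            buf = io.StringIO()
            write_wide_table(self.rows, self.schema, buf,
                             delimiter=delimiter, allow_bags=allow_bags)
            return buf.getvalue()
        return write_wide_table(self.rows, self.schema, sink,
                                delimiter=delimiter, allow_bags=allow_bags)

    def to_dataframe(self):
        import pandas as pd

        data = []
        for row in sorted(self.rows, key=lambda r: r.key):
            rec = dict(zip(self.schema[: len(row.key)], row.key))
            for col in self.schema[len(row.key):]:
                rec[col] = row.cells.get(col)
            data.append(rec)
        return pd.DataFrame(data, columns=list(self.schema))


# Module-level so the reduce closure pickles under the fork-pool contract.
@dataclass(frozen=True)
class _PipelineMap:
    catalog_codes: frozenset
    key_fields: tuple[str, ...]

    def __call__(self, record: EventRecord):
        if record.code not in self.catalog_codes:
            return ()
        key = tuple(
            (record.subject_id if f == "subject_id" else (record.episode_id or ""))
            for f in self.key_fields
        )
        return ((key, record),)


@dataclass(frozen=True)
class _PipelineReduce:
    catalog: GroupCatalog
    aggspec: tuple  # ((group, AggEntry), ...) in declaration order
    pickup: tuple  # ((group, PickupSpec), ...)
    summary_index: tuple  # ((key, SummaryRecord), ...) or None marker
    join_summaries: bool

    def __call__(self, key, bag):
        row = inner_group(key, bag, self.catalog)
        if self.pickup:
            anchors = dict(self.summary_index) if self.join_summaries else {}
            summary = anchors.get(key)
            for group, spec in self.pickup:
                if summary is None:
                    row.cells[group] = []
                else:
                    row.cells[group] = pickup_sequence_values(
                        row.cells[group],
                        summary.admission_date,
                        spec.period_days,
                        max_gap=spec.max_gap,
                    )
        cells = {}
        for group, entry in self.aggspec:
            cells[group] = aggregate(row.cells[group], entry, self.catalog, group)
        return (WideRow(key=key, cells=cells),)


def _summary_key(summary: SummaryRecord, key_fields: tuple[str, ...]) -> tuple:
    return tuple(
        (summary.subject_id if f == "subject_id" else summary.episode_id)
        for f in key_fields
    )


def run_pipeline(
    events: Iterable[EventRecord],
    catalog: GroupCatalog,
    key_fields: Sequence[str],
    aggspec: AggregationSpec,
    summaries: Iterable[SummaryRecord] | None = None,
    *,
    workers: int = 1,
    shard_size: int = 50_000,
    shards: Sequence[Sequence[EventRecord]] | None = None,
    pickup: dict[str, PickupSpec] | None = None,
    two_phase: bool = False,
    stats: dict | None = None,
) -> WideTable:
    """Run the whole long-to-wide transformation as one engine job.

    The map phase drops undefined codes (the exists filter) and extracts
    the grouping key; the reduce phase pivots each key's bag into
    per-group cells, applies any consecutive-run date filters, joins
    catalog values, and aggregates.  When discharge summaries are
    supplied their fields (admission/discharge dates, sex, age at
    admission) are joined onto each key's row, and every summary key gets
    a row even if it has no surviving events.

    ``two_phase=True`` runs the pivot and the aggregation as two separate
    reduce passes (the historical structure of cluster implementations
    needing one reduce per stage); output is identical.
    """
    for f in key_fields:
        if f not in ("subject_id", "episode_id"):
            raise InvalidParamsError(f"unknown key field {f!r}")
    key_fields = tuple(key_fields)
    pickup = pickup or {}
    for group in pickup:
        if group not in catalog.group_names:
            raise InvalidParamsError(f"pickup filter names unknown group {group!r}")

    summary_list = list(summaries) if summaries is not None else None
    if pickup and summary_list is None:
        raise InvalidParamsError(
            "pickup date filters need discharge summaries for the anchor date"
        )

    # one summary per key: earliest admission wins (relevant when the key
    # is the subject alone but the subject has several episodes)
    summary_by_key: dict = {}
    if summary_list is not None:
        for s in sorted(summary_list,
                        key=lambda s: (s.admission_date, s.episode_id)):
            summary_by_key.setdefault(_summary_key(s, key_fields), s)

    ordered_agg = tuple((name, aggspec[name]) for name in catalog.group_names)
    map_fn = _PipelineMap(catalog.codes, key_fields)
    reduce_fn = _PipelineReduce(
        catalog=catalog,
        aggspec=ordered_agg,
        pickup=tuple(sorted(pickup.items())),
        summary_index=tuple(sorted(summary_by_key.items())),
        join_summaries=summary_list is not None,
    )

    job_stats: dict = {}
    if not two_phase:
        rows = run_job(
            events,
            MapReduceJob(map_fn, reduce_fn, workers=workers, shard_size=shard_size),
            shards=shards,
            stats=job_stats,
        )
    else:
        pivot_fn = _PivotOnlyReduce(
            catalog=catalog,
            pickup=tuple(sorted(pickup.items())),
            summary_index=tuple(sorted(summary_by_key.items())),
            join_summaries=summary_list is not None,
        )
        bag_rows = run_job(
            events,
            MapReduceJob(map_fn, pivot_fn, workers=workers, shard_size=shard_size),
            shards=shards,
            stats=job_stats,
        )
        agg_fn = _AggOnlyReduce(catalog=catalog, aggspec=ordered_agg)
        rows = run_job(
            bag_rows,
            MapReduceJob(_rekey_wide_row, agg_fn, workers=workers,
                         shard_size=shard_size),
        )

    by_key = {row.key: row for row in rows}
    if summary_list is not None:
        empty = {name: aggregate([], entry, catalog, name)
                 for name, entry in ordered_agg}
        for key in summary_by_key:
            if key not in by_key:
                by_key[key] = WideRow(key=key, cells=dict(empty))
        for key, row in by_key.items():
            summary = summary_by_key.get(key)
            if summary is not None:
                row.cells["admission_date"] = summary.admission_date
                row.cells["discharge_date"] = summary.discharge_date
                row.cells["sex"] = summary.sex
                row.cells["age"] = age_in_years(
                    summary.birth_date, summary.admission_date
                )

    schema = key_fields
    if summary_list is not None:
        schema = schema + SUMMARY_COLUMNS
    schema = schema + catalog.group_names

    if stats is not None:
        stats.update(job_stats)
        stats["n_output_rows"] = len(by_key)
    return WideTable(schema=schema,
                     rows=[by_key[k] for k in sorted(by_key)])


@dataclass(frozen=True)
class _PivotOnlyReduce:
    catalog: GroupCatalog
    pickup: tuple
    summary_index: tuple
    join_summaries: bool

    def __call__(self, key, bag):
        row = inner_group(key, bag, self.catalog)
        if self.pickup:
            anchors = dict(self.summary_index) if self.join_summaries else {}
            summary = anchors.get(key)
            for group, spec in self.pickup:
                if summary is None:
                    row.cells[group] = []
                else:
                    row.cells[group] = pickup_sequence_values(
                        row.cells[group], summary.admission_date,
                        spec.period_days, max_gap=spec.max_gap,
                    )
        return (row,)


def _rekey_wide_row(row: WideRow):
    return ((row.key, row),)


@dataclass(frozen=True)
class _AggOnlyReduce:
    catalog: GroupCatalog
    aggspec: tuple

    def __call__(self, key, bag):
        (row,) = bag
        cells = {}
        for group, entry in self.aggspec:
            cells[group] = aggregate(row.cells[group], entry, self.catalog, group)
        return (WideRow(key=key, cells=cells),)
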