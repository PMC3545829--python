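"""Map→shuffle→reduce executor: correctness, determinism, invariance."""

import datetime as dt
import random

import pytest

from widetab.engine import MapReduceJob, PickupSpec, run_job, run_pipeline
from widetab.errors import InvalidParamsError, MapError, ReduceError
from widetab.gff import parse_gff
from widetab.records_io import EventRecord, SummaryRecord
from widetab.transform import parse_aggspec

from oracle_utils import oracle_pivot

D = dt.date


def _key_by_code(record):
    return ((record.code,), record),


def _count_reduce(key, bag):
    return ((key[0], len(bag)),)


def ev(subject, code, day, quantity=1.0):
    return EventRecord(subject, "E1", D(2012, 1, day), code, quantity)


class TestRunJob:
    RECORDS = [ev("P1", c, d) for c, d in
               [("a", 1), ("b", 2), ("a", 3), ("c", 4), ("b", 5), ("a", 6)]]

    def test_count_by_code_matches_hand_tally(self):
        job = MapReduceJob(_key_by_code, _count_reduce)
        assert run_job(self.RECORDS, job) == [("a", 3), ("b", 2), ("c", 1)]

    def test_empty_input(self):
        job = MapReduceJob(_key_by_code, _count_reduce)
        assert run_job([], job) == []

    @pytest.mark.parametrize("workers", [1, 2, 4])
    def test_output_invariant_to_worker_count(self, workers):
        job = MapReduceJob(_key_by_code, _count_reduce, workers=workers,
                           shard_size=2)
        assert run_job(self.RECORDS, job) == [("a", 3), ("b", 2), ("c", 1)]

    def test_output_invariant_to_sharding(self):
        job = MapReduceJob(_key_by_code, _count_reduce)
        reference = run_job(self.RECORDS, job)
        rng = random.Random(3)
        for _ in range(10):
            cuts = sorted(rng.sample(range(1, len(self.RECORDS)),
                                     rng.randint(0, 4)))
            shards, at = [], 0
            for cut in cuts + [len(self.RECORDS)]:
                shards.append(self.RECORDS[at:cut])
                at = cut
            assert run_job(self.RECORDS, job, shards=shards) == reference

    def test_exactly_once_accounting(self):
        stats = {}
        job = MapReduceJob(_key_by_code, _count_reduce, shard_size=2)
        run_job(self.RECORDS, job, stats=stats)
        assert stats["n_input"] == len(self.RECORDS)
        assert stats["n_mapped"] == stats["reduce_input_total"]
        assert stats["n_keys"] == 3

    def test_map_error_names_shard(self):
        def bad_map(record):
            raise RuntimeError("boom")

        job = MapReduceJob(bad_map, _count_reduce, shard_size=2)
        with pytest.raises(MapError, match="shard 0"):
            run_job(self.RECORDS, job)

    def test_reduce_error_names_key(self):
        def bad_reduce(key, bag):
            raise RuntimeError("boom")

        job = MapReduceJob(_key_by_code, bad_reduce)
        with pytest.raises(ReduceError, match="'a'"):
            run_job(self.RECORDS, job)

    def test_invalid_worker_count(self):
        with pytest.raises(InvalidParamsError):
            MapReduceJob(_key_by_code, _count_reduce, workers=0)


CATALOG_TEXT = "g1 (a [10, 1]), g2 (b [20, 2], c [30, 3]), g3 (a [40, 4])"


def _groups_structured():
    return [
        ("g1", {"a": (10, 1)}),
        ("g2", {"b": (20, 2), "c": (30, 3)}),
        ("g3", {"a": (40, 4)}),
    ]


class TestRunPipeline:
    def _events(self, seed, n=60):
        rng = random.Random(seed)
        return [
            EventRecord(f"P{rng.randint(1, 5)}", "E1",
                        D(2012, 1, rng.randint(1, 28)),
                        rng.choice(["a", "b", "c", "zz"]),
                        float(rng.randint(1, 3)))
            for _ in range(n)
        ]

    def test_matches_nested_loop_oracle(self):
        catalog = parse_gff(CATALOG_TEXT)
        agg_text = "g1=COUNT,g2=SUM@0,g3=SUM@qty"
        events = self._events(11)
        table = run_pipeline(events, catalog, ("subject_id", "episode_id"),
                             parse_aggspec(agg_text, catalog))
        expected = oracle_pivot(events, _groups_structured(), agg_text)
        got = {row.key: {g: row.cells[g] for g in catalog.group_names}
               for row in table.rows}
        assert got == expected

    def test_empty_catalog_intersection_with_summaries(self):
        catalog = parse_gff("g1 (never1), g2 (never2)")
        events = self._events(5)
        summaries = [
            SummaryRecord(f"P{i}", "E1", D(2012, 1, 1), D(2012, 1, 9),
                          D(1950, 1, 1), "F")
            for i in (1, 2, 3)
        ]
        table = run_pipeline(events, catalog, ("subject_id", "episode_id"),
                             parse_aggspec("", catalog), summaries=summaries)
        assert len(table.rows) == 3
        assert all(row.cells["g1"] == 0 and row.cells["g2"] == 0
                   for row in table.rows)
        # without summaries there is nothing to hang a row on
        empty = run_pipeline(events, catalog, ("subject_id", "episode_id"),
                             parse_aggspec("", catalog))
        assert empty.rows == []

    def test_duplicating_events_doubles_counts(self):
        catalog = parse_gff(CATALOG_TEXT)
        events = self._events(9)
        spec = parse_aggspec("", catalog)
        once = run_pipeline(events, catalog, ("subject_id",), spec)
        twice = run_pipeline(events + events, catalog, ("subject_id",), spec)
        for row1, row2 in zip(once.rows, twice.rows):
            assert row1.key == row2.key
            for g in catalog.group_names:
                assert row2.cells[g] == 2 * row1.cells[g]

    def test_summary_join_adds_demographics(self):
        catalog = parse_gff(CATALOG_TEXT)
        events = [ev("P1", "a", 5)]
        summaries = [SummaryRecord("P1", "E1", D(2012, 1, 1), D(2012, 1, 9),
                                   D(1950, 6, 15), "M")]
        table = run_pipeline(events, catalog, ("subject_id", "episode_id"),
                             parse_aggspec("", catalog), summaries=summaries)
        (row,) = table.rows
        assert row.cells["sex"] == "M"
        assert row.cells["age"] == 61
        assert table.schema[:6] == ("subject_id", "episode_id",
                                    "admission_date", "discharge_date",
                                    "sex", "age")

    def test_pickup_filter_keeps_anchored_run_only(self):
        catalog = parse_gff("med (a)")
        summaries = [SummaryRecord("P1", "E1", D(2012, 1, 1), D(2012, 1, 20),
                                   D(1950, 1, 1), "F")]
        events = [ev("P1", "a", d) for d in (1, 2, 3, 6)]  # offsets 0,1,2,5
        table = run_pipeline(
            events, catalog, ("subject_id", "episode_id"),
            parse_aggspec("", catalog), summaries=summaries,
            pickup={"med": PickupSpec(period_days=7)},
        )
        (row,) = table.rows
        assert row.cells["med"] == 3

    def test_pickup_without_summaries_rejected(self):
        catalog = parse_gff("med (a)")
        with pytest.raises(InvalidParamsError):
            run_pipeline([], catalog, ("subject_id",),
                         parse_aggspec("", catalog),
                         pickup={"med": PickupSpec(period_days=7)})

    def test_two_phase_equals_single_phase(self):
        catalog = parse_gff(CATALOG_TEXT)
        events = self._events(21)
        spec = parse_aggspec("g1=COUNT,g2=SUM@1,g3=COUNT", catalog)
        single = run_pipeline(events, catalog, ("subject_id",), spec)
        double = run_pipeline(events, catalog, ("subject_id",), spec,
                              two_phase=True)
        assert single.to_tsv() == double.to_tsv()
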