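"""Pivot primitives: filter, inner grouping, value join, aggregation."""

import datetime as dt

import pytest

from widetab.errors import (
    EmptyCellError,
    InvalidParamsError,
    MissingValuesError,
    NonNumericCellError,
    ValueIndexOutOfRangeError,
)
from widetab.gff import parse_gff
from widetab.records_io import EventRecord
from widetab.transform import (
    AggEntry,
    aggregate,
    exists_filter,
    exposure_within_window,
    first_last_interval,
    inner_group,
    parse_aggspec,
    value_join,
)

D = dt.date


def ev(code, day, subject="P1", quantity=1.0):
    return EventRecord(subject, "E1", D(2012, 1, day), code, quantity)


class TestExistsFilter:
    def test_drops_undefined_codes_and_counts(self, abx_catalog):
        records = [ev("c1", 1), ev("zz", 2), ev("c2", 3), ev("yy", 4), ev("c3", 5)]
        stream = exists_filter(records, abx_catalog)
        kept = list(stream)
        assert [r.code for r in kept] == ["c1", "c2", "c3"]
        assert stream.n_dropped == 2
        assert stream.n_kept == 3

    def test_empty_intersection_annihilates(self, abx_catalog):
        records = [ev("zz", 1), ev("yy", 2)]
        stream = exists_filter(records, abx_catalog)
        assert list(stream) == []
        assert stream.n_dropped == 2

    def test_all_defined_is_identity(self, abx_catalog):
        records = [ev("c1", 1), ev("c2", 2)]
        assert list(exists_filter(records, abx_catalog)) == records


class TestInnerGroup:
    def test_pivots_by_group(self):
        cat = parse_gff("g1 (a), g2 (b, c)")
        records = [ev("a", 1), ev("c", 2), ev("a", 3)]
        row = inner_group(("P1",), records, cat)
        assert len(row.cells["g1"]) == 2
        assert len(row.cells["g2"]) == 1

    def test_empty_bag_gives_all_empty_cells(self):
        cat = parse_gff("g1 (a), g2 (b)")
        row = inner_group(("P1",), [], cat)
        assert row.cells == {"g1": [], "g2": []}

    def test_shared_code_lands_in_both_groups(self, shared_code_catalog):
        records = [ev("a", 1), ev("b", 2)]
        row = inner_group(("P1",), records, shared_code_catalog)
        assert [e.code for e in row.cells["g1"]] == ["a"]
        assert [e.code for e in row.cells["g2"]] == ["a", "b"]

    def test_cells_ordered_by_date_then_code(self):
        cat = parse_gff("g (a, b)")
        records = [ev("b", 5), ev("a", 5), ev("b", 1)]
        row = inner_group(("P1",), records, cat)
        assert [(e.code, e.event_date.day) for e in row.cells["g"]] == [
            ("b", 1), ("a", 5), ("b", 5)
        ]


class TestValueJoin:
    def test_join_at_each_index(self, abx_catalog):
        cell = [ev("c1", 1), ev("c2", 2)]
        assert [v for _, v in value_join(cell, abx_catalog, "abx", 0)] == [100.0, 50.0]
        assert [v for _, v in value_join(cell, abx_catalog, "abx", 1)] == [200.0, 75.0]

    def test_index_out_of_range(self, abx_catalog):
        with pytest.raises(ValueIndexOutOfRangeError):
            value_join([ev("c1", 1)], abx_catalog, "abx", 2)

    def test_missing_values(self):
        cat = parse_gff("g (a)")
        with pytest.raises(MissingValuesError):
            value_join([ev("a", 1)], cat, "g", 0)


class TestAggregate:
    def test_count(self, abx_catalog):
        cell = [ev("c1", d) for d in (1, 2, 3)]
        assert aggregate(cell, AggEntry("COUNT"), abx_catalog, "abx") == 3
        assert aggregate([], AggEntry("COUNT"), abx_catalog, "abx") == 0

    def test_sum_over_joined_values(self, abx_catalog):
        cell = [ev("c1", 1), ev("c1", 2), ev("c2", 3)]
        entry = AggEntry("SUM", ("value", 0))
        assert aggregate(cell, entry, abx_catalog, "abx") == 250.0

    def test_sum_over_quantities(self, abx_catalog):
        cell = [ev("c1", 1, quantity=2.0), ev("c2", 2, quantity=3.5)]
        assert aggregate(cell, AggEntry("SUM", ("quantity",)),
                         abx_catalog, "abx") == 5.5

    def test_empty_bag_rules(self, abx_catalog):
        assert aggregate([], AggEntry("SUM", ("value", 0)), abx_catalog, "abx") == 0.0
        assert aggregate([], AggEntry("MAX", ("value", 0)), abx_catalog, "abx") is None
        assert aggregate([], AggEntry("FIRST_DATE"), abx_catalog, "abx") is None

    def test_first_last_dates(self, abx_catalog):
        cell = [ev("c1", 9), ev("c2", 2), ev("c1", 5)]
        assert aggregate(cell, AggEntry("FIRST_DATE"), abx_catalog, "abx") == D(2012, 1, 2)
        assert aggregate(cell, AggEntry("LAST_DATE"), abx_catalog, "abx") == D(2012, 1, 9)

    def test_permutation_invariance(self, abx_catalog):
        import itertools

        cell = [ev("c1", 1), ev("c2", 5), ev("c1", 3)]
        entry = AggEntry("SUM", ("value", 1))
        results = {
            (aggregate(list(p), AggEntry("COUNT"), abx_catalog, "abx"),
             aggregate(list(p), entry, abx_catalog, "abx"))
            for p in itertools.permutations(cell)
        }
        assert len(results) == 1

    def test_extremum_idempotent_under_duplication(self, abx_catalog):
        cell = [ev("c1", 1), ev("c2", 2)]
        entry = AggEntry("MAX", ("value", 0))
        top = aggregate(cell, entry, abx_catalog, "abx")
        assert aggregate(cell + [ev("c1", 3)], entry, abx_catalog, "abx") == top

    def test_numeric_agg_without_source_rejected(self):
        with pytest.raises(InvalidParamsError):
            AggEntry("SUM")

    def test_quantity_source_requires_quantities(self, abx_catalog):
        cell = [EventRecord("P1", "E1", D(2012, 1, 1), "c1", None)]
        with pytest.raises(NonNumericCellError):
            aggregate(cell, AggEntry("SUM", ("quantity",)), abx_catalog, "abx")


class TestParseAggspec:
    def test_defaults_to_count_everywhere(self, abx_catalog):
        spec = parse_aggspec("", abx_catalog)
        assert set(spec) == {"abx", "ppi"}
        assert all(entry.op == "COUNT" for entry in spec.values())

    def test_value_and_quantity_sources(self, abx_catalog):
        spec = parse_aggspec("abx=SUM@1, ppi=SUM@qty", abx_catalog)
        assert spec["abx"] == AggEntry("SUM", ("value", 1))
        assert spec["ppi"] == AggEntry("SUM", ("quantity",))

    @pytest.mark.parametrize("text", [
        "nosuch=COUNT", "abx=BOGUS", "abx=COUNT,abx=SUM@0", "abx=SUM@x",
    ])
    def test_bad_specs_rejected(self, text, abx_catalog):
        with pytest.raises(InvalidParamsError):
            parse_aggspec(text, abx_catalog)


class TestDerivedVariables:
    def test_first_last_interval(self):
        cell = [ev("c1", 2), ev("c1", 5)]
        assert first_last_interval(cell) == 3
        assert first_last_interval([ev("c1", 4)]) == 0
        assert first_last_interval(list(reversed(cell))) == 3
        with pytest.raises(EmptyCellError):
            first_last_interval([])

    @pytest.mark.parametrize("event_day, window, expected", [
        (3, 3, True),    # offset 2 within 3 days after index
        (5, 3, False),   # offset 4 beyond the window
        (1, 0, True),    # event on the index date, zero-width window
    ])
    def test_exposure_window_inclusive(self, event_day, window, expected):
        index = D(2012, 1, 1)
        cell = [ev("c1", event_day)]
        assert exposure_within_window(cell, index, window) is expected

    def test_exposure_day0_exclusion_flag(self):
        index = D(2012, 1, 1)
        cell = [ev("c1", 1)]
        assert exposure_within_window(cell, index, 3, include_day0=False) is False
        assert not exposure_within_window([ev("c1", 1)], D(2012, 1, 2), 3)
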