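# widetab

Transform long-format administrative health data — medical activity logs
and discharge summaries, one event per row — into the wide table format
(one row per patient or admission, one column per derived variable) that
statistical software expects.  widetab is aimed at epidemiologists and
health-services researchers working with claims-style data who want
declarative cohort construction: which codes form which variable, which
numeric value attaches to each code, which date windows matter.

It provides:

* **GroupFilterFormat catalogs** — a tiny declarative language mapping
  raw item codes (e.g. pharmaceutical product codes) into named
  wide-table fields with optional numeric value attachments:

  ```
  antibiotic (MED001 [25, 5], MED002 [50, 8.7]), analgesic (MED005 [500, 19.8])
  ```

  reads as: codes MED001/MED002 form the `antibiotic` column, each with a
  (unit dose, unit price) pair; MED005 forms `analgesic`.

* **A local map→shuffle→reduce engine** with the phase structure of a
  cluster job: the map phase drops events whose code the catalog does not
  define and extracts the grouping key; the reduce phase pivots each
  key's bag of events into per-group cells, joins the catalog's numeric
  values onto matched events, applies date filters, and aggregates
  (COUNT, SUM, MAX, MIN, first/last date).  Output is byte-identical
  regardless of worker count or input sharding.

* **Date functions** for cohort logic: exact signed day intervals and
  date shifting (`get_day_span`, `add_day_span`), completed-years age,
  exposure-within-window predicates ("antibiotics within three days after
  surgery"), and `pickup_sequence_values`, which extracts the run of
  consecutive daily administrations anchored at a start date.

* **A seeded synthetic workload generator** (discharge summaries plus a
  medication log over a 20-code roster with Zipf-like code frequencies,
  Poisson event counts and injected consecutive-administration courses)
  and **a benchmark harness** fitting the two scaling models: linear
  time-vs-records, `t = a·x + b`, and power-law time-vs-workers,
  `t = c·w^e`, with the per-doubling consequence `(1 − 2^e)·100 %`.

## Worked example

Generate a toy dataset, then pivot it:

```sh
$ widetab synth --patients 5 --seed 7 --out-dir demo/
$ widetab transform --gff demo/catalog.gff --events demo/events.tsv \
      --summary demo/summary.tsv \
      --agg "antibiotic=COUNT,analgesic=SUM@0" --out demo/wide.tsv
7 rows × 11 columns -> demo/wide.tsv
```

A slice of `demo/wide.tsv`:

```
subject_id  episode_id  sex  age  antibiotic  analgesic  anticoagulant
P0000001    E0000001_1  M    11   13          1535       1
P0000001    E0000001_2  M    12   12          510        0
P0000002    E0000002_1  M    50   24          600        3
```

Each row is one admission episode.  `sex` and `age` (completed years at
admission) are joined from the discharge summary.  `antibiotic=COUNT`
counts administrations of any antibiotic-class code during the episode
(13 for the first episode); `analgesic=SUM@0` sums the value at index 0
— the unit dose — that the catalog attaches to each administered
analgesic code (1535 dose units); `anticoagulant` defaults to COUNT.
Aggregations take `OP@k` for the catalog value at index k and `OP@qty`
for the event's own quantity column.  `--pickup group:period[:max_gap]`
restricts a group to the consecutive daily run anchored at admission
before aggregating, and `--workers N` runs the same job on N processes
with identical output.

The same pipeline is available as a library:

```python
from widetab import parse_gff, read_events, read_summaries, run_pipeline, parse_aggspec

catalog = parse_gff(open("demo/catalog.gff").read())
table = run_pipeline(
    read_events("demo/events.tsv"), catalog, ("subject_id", "episode_id"),
    parse_aggspec("antibiotic=COUNT,analgesic=SUM@0", catalog),
    summaries=list(read_summaries("demo/summary.tsv")),
)
df = table.to_dataframe()
```

## Benchmarks

```sh
widetab bench speed   --patients 2000 --reps 3 --out speed.tsv
widetab bench scaling --patients 2000 --reps 3 --workers-list 1,2,4 --out scaling.tsv
```

Each writes a per-point mean/max/min table and the fitted model line
(linear for speed, power-law for scaling, with the per-doubling
percentage).  Wall-clock numbers are machine-dependent; the analysis
object is the fitted relationship.  See `docs/methods.md` for the models,
the generator's assumptions, and numerical conventions.

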