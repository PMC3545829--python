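# Methods

## Problem and model

Administrative health data — discharge summaries and activity logs from
claims or inpatient databases — arrive in long format: one row per medical
activity (a drug administration, a procedure), many rows per patient.
Epidemiological analysis wants wide format: one row per analysis unit
(patient or admission episode), one column per derived variable.  widetab
performs that reshape with the phase structure of a MapReduce job, so the
same program logic describes both a desk-scale run and the shape of a
cluster run:

1. **Map** — each event record is checked against the catalog (the
   *exists* filter: events whose code the catalog does not define are
   dropped, reducing volume early) and keyed by the grouping fields.
2. **Shuffle** — events are grouped by key; every key's events form one
   bag presented to exactly one reduce invocation.
3. **Reduce** — the bag is pivoted into per-group cells (*inner group*),
   optional consecutive-run date filters are applied, catalog-attached
   numeric values are joined onto matched events (*value join*), and each
   cell is collapsed by its aggregation (COUNT, SUM, MAX, MIN, first/last
   event date, or the raw bag).

The catalog language ("GroupFilterFormat") is the declarative heart:
`groupname (item1 [value1, value2, ...], item2, ...), ...` maps raw item
codes into named wide-table fields and attaches per-item numeric values
(unit dose, price, ...).  The grammar implemented is the minimal one
consistent with that template: names and codes are maximal runs of
characters excluding `, ( ) [ ]` and whitespace; numbers are signed
decimals; newlines are whitespace.  There is deliberately no quoting or
escaping — codes containing delimiters are rejected with a line/column
error rather than guessed at.  A code may belong to several groups (each
membership with its own values), which re-categorization workflows need;
within one group a code may appear only once.  Values are attached per
item *within* a group, not globally per code, following the template's
nesting.

## Date functions

All date arithmetic runs on proleptic-Gregorian day ordinals, so
`get_day_span`/`add_day_span` are exact integer operations satisfying the
inverse law `get_day_span(d, add_day_span(d, n)) = n`.

`pickup_sequence_values(events, start, period_days)` extracts the maximal
gap-free daily run anchored at `start` and truncated at
`period_days` — the "drug administered every day from admission" pattern.
Decisions made where more than one reading existed:

* "consecutively" is read strictly as a zero-gap daily run; a `max_gap`
  parameter (default 0) relaxes it, since real prescribing data has
  weekend gaps, without changing default behaviour;
* the period window is closed, `[start, start + period_days − 1]`: the
  period counts the start day;
* if no event falls on the start date the result is empty (the run is
  anchored);
* the rule operates on days, not events: all events of an included day
  are kept together.

`age_in_years` counts completed calendar years; a Feb 29 birthday's
anniversary is taken as Mar 1 in non-leap years (one convention had to be
picked; this is the common administrative one).

`exposure_within_window` (the "antibiotics within three days after
surgery" predicate) uses inclusive offsets `0..window_days`; an
`include_day0=False` flag shifts the lower bound for the reading "after,
not on, the index day".

## Engine determinism

Output is invariant to worker count and input sharding by construction:
shards are mapped in order, each key's bag preserves map-output order,
reduce runs over keys in sorted order, bags inside the pivot are sorted by
(date, code, input order), and rows are emitted (and written) in key
order.  The empirical tests then confirm byte-identical output at 1, 2, 4
and 8 workers and under random shardings.

The parallel backend uses fork-based process pools: workers receive shard
or key-block *indices* and inherit the input through the fork, so
inter-process traffic carries results only, there is no shared mutable
state, and all communication flows through the shuffle.  `workers=1` is
the plain sequential reference path.

The pivot and the aggregation run inside a single reduce phase by
default: since the aggregation is per-key, nothing forces a second
shuffle.  `two_phase=True` runs them as two separate reduce passes — the
historical structure of cluster implementations that needed one reduce
per stage — and is tested to produce identical output.

Aggregation conventions fixed for byte-determinism of output: empty bags
give COUNT 0 and SUM 0 but an empty cell for MAX/MIN/first/last date;
integral floats print without a fraction; dates print ISO.

## Synthetic workload

The generator emulates the benchmark composition — discharge summaries
plus a medication activity log over a 20-code roster, many events per
patient — at configurable scale.  It is workload emulation, not patient
simulation.  Distributions (all parameters with defaults, all seeded
through one `numpy` generator):

* per-patient admission count: 1 + Poisson(mean − 1), default mean 1.2;
* per-patient event count: Poisson(mean), default 40, split across the
  patient's admissions multinomially; `paper_ratio=True` switches the
  mean to ≈413 events/patient, the ratio of 950 million events to 2.3
  million inpatients in the benchmark composition;
* admission dates uniform over a three-year window; length of stay
  log-normal (median 7 days, σ = 0.6); event dates uniform within the
  admission window, so every event lies inside its episode;
* medication codes drawn from the roster with Zipf-like (1/rank)
  frequencies;
* with probability 0.3 per eligible admission, part of the admission's
  event budget is converted into an injected *course*: 3–10 consecutive
  daily administrations of one code, recorded as ground truth so
  consecutive-run extraction has known structure to recover.  Courses are
  carved out of the Poisson budget, not added to it, so total event
  counts keep the Poisson mean.

The default catalog partitions the roster into five therapeutic classes
of four codes, each item carrying a (unit dose, unit price) value pair so
numeric joins are exercisable at indices 0 and 1.

What the generator does **not** emulate: diagnosis codes, comorbidity
structure, seasonal admission patterns, code co-occurrence, or any
clinical correlation between medications and demographics.  Passing tests
therefore demonstrate the *mechanics* of transformation on realistically
shaped volumes and key distributions, not epidemiological validity of any
derived variable.

## Benchmarks and regression models

Two protocols: processing time vs record count at fixed workers (by-patient
subsamples at fractions 1, 1/2, 1/4, 1/8 of the dataset, several
repetitions each) and processing time vs worker count on the full sample.
Expected relationships: linear `t = a·x + b` for the speed protocol (the
intercept is the fixed job lead time) and power-law `t = c·w^e` for
scaling, `e = −1` being ideal linear speed-up.  The per-doubling
consequence of an exponent is `(1 − 2^e) × 100` percent.

The linear model is ordinary least squares; the power model is OLS on
log t vs log x, with R² reported on the log scale (the standard choice for
log–log fits; fits on per-trial points and on per-point averages give
slightly different intercepts, and the harness supports both).  Degenerate
designs (fewer than two distinct x) and non-positive values for the power
fit are rejected.  When the residuals vanish on a zero-variance response,
R² is defined as 1 (a perfect fit of a flat line).

Wall-clock numbers are machine-dependent and are never asserted against
any external value; tests assert the regression machinery (exact
coefficient recovery on noise-free curves at the published design points,
coverage under noise), table shapes, and the analytic per-doubling
consequence.  Default problem sizes — 10,000 patients at a mean of 40
events (≈ 4×10⁵ events) for the reference workload, smaller for unit
tests — were chosen so a full suite run stays in the minutes range on one
core while the determinism and conservation properties are exercised well
above toy scale.

On a single-core machine, process-level parallelism cannot reduce elapsed
time, and at desk scale the per-record computation is cheap enough that
inter-process serialization dominates; worker counts above the available
core count are therefore outside the scaling claim, which is stated "up
to the available core count" in the tests.

## Known limitations

* No distributed filesystem, fault tolerance, or multi-machine operation:
  the engine is a local executor with the cluster phase *contract*.
* The catalog language has no quoting, wildcards, or ontology/hierarchy
  resolution (e.g. ATC trees); grouping is by exact code.
* `read_events` accepts only ISO and compact dates; no locale dialects.
* Summary join with a subject-only key picks the earliest admission when
  a subject has several episodes; episode-level keys avoid the choice.
* Statistical modelling of the resulting wide table (regression,
  matching) is downstream and out of scope.
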