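"""Seeded generator of dummy discharge summaries and medication logs.

The generator emulates the structure of an in-hospital administrative
benchmark workload: discharge summaries (one row per admission episode)
plus a medication activity log drawing on a fixed roster of 20 medication
codes, many events per patient.  It is workload emulation, not patient
simulation — codes follow a Zipf-like frequency profile, per-patient event
counts are Poisson, admission dates are uniform and lengths of stay
log-normal, and a share of admissions carry an injected "course": a run of
consecutive daily administrations of one code, so consecutive-run
extraction has non-trivial structure to find.

Generation is a pure function of the parameters: the same ``SynthParams``
always produce byte-identical files.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dates import add_day_span, get_day_span
from .errors import InvalidParamsError
from .gff import GroupCatalog, GroupSpec, ItemSpec, write_gff
from .records_io import EventRecord, SummaryRecord, write_events, write_summaries

__all__ = [
    "SynthParams",
    "InjectedCourse",
    "SynthDataset",
    "default_catalog",
    "generate",
    "generate_dataset",
    "write_dataset",
]

#: events per patient implied by the benchmark composition of 950 million
#: activity-log events over 2.3 million inpatients
PAPER_EVENTS_PER_PATIENT = 950_000_000 / 2_300_000  # ≈ 413

_CLASS_NAMES = (
    "antibiotic",
    "analgesic",
    "anticoagulant",
    "antihypertensive",
    "antidiabetic",
    "diuretic",
    "antiemetic",
    "sedative",
)

_UNIT_DOSES = (25.0, 50.0, 100.0, 250.0, 500.0, 10.0)


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the synthetic workload.

    Desk-scale defaults (10,000 patients at a mean of 40 events each,
    ≈ 4×10⁵ events) keep full runs fast; ``paper_ratio=True`` switches the
    event mean to the benchmark composition's ≈ 413 events per patient.
    """

    n_patients: int = 10_000
    mean_admissions_per_patient: float = 1.2
    mean_events_per_patient: float = 40.0
    n_medication_codes: int = 20
    date_start: dt.date = dt.date(2010, 1, 1)
    date_end: dt.date = dt.date(2012, 12, 31)
    seed: int = 0
    course_probability: float = 0.3
    paper_ratio: bool = False

    def __post_init__(self):
        if self.n_patients < 0:
            raise InvalidParamsError("n_patients must be ≥ 0")
        if self.mean_admissions_per_patient < 1:
            raise InvalidParamsError("mean_admissions_per_patient must be ≥ 1")
        if self.mean_events_per_patient <= 0:
            raise InvalidParamsError("mean_events_per_patient must be > 0")
        if self.n_medication_codes < 1:
            raise InvalidParamsError("n_medication_codes must be ≥ 1")
        if self.date_start >= self.date_end:
            raise InvalidParamsError("date_start must precede date_end")
        if not 0 <= self.course_probability <= 1:
            raise InvalidParamsError("course_probability must be in [0, 1]")

    @property
    def event_mean(self) -> float:
        return (PAPER_EVENTS_PER_PATIENT if self.paper_ratio
                else self.mean_events_per_patient)


@dataclass(frozen=True)
class InjectedCourse:
    """Ground truth for one injected consecutive administration run."""

    subject_id: str
    episode_id: str
    code: str
    start_date: dt.date
    length_days: int


@dataclass
class SynthDataset:
    summaries: list[SummaryRecord]
    events: list[EventRecord]
    courses: list[InjectedCourse]
    params: SynthParams


def _code(i: int) -> str:
    return f"MED{i + 1:03d}"


def default_catalog(params: SynthParams) -> GroupCatalog:
    """A catalog partitioning the medication roster into therapeutic classes.

    Codes are split into contiguous blocks over at most eight class names
    (five groups of four for the default 20-code roster); every item
    carries a (unit dose, unit price) value pair so numeric joins can be
    exercised at indices 0 and 1.
    """
    n = params.n_medication_codes
    n_groups = min(len(_CLASS_NAMES), max(1, min(5, n)))
    per_group = math.ceil(n / n_groups)
    groups = []
    for g in range(n_groups):
        items = []
        for i in range(g * per_group, min((g + 1) * per_group, n)):
            dose = _UNIT_DOSES[i % len(_UNIT_DOSES)]
            price = round(5.0 + 3.7 * i, 2)
            items.append(ItemSpec(_code(i), (dose, price)))
        if items:
            groups.append(GroupSpec(_CLASS_NAMES[g], tuple(items)))
    return GroupCatalog(groups)


def _zipf_probs(n: int) -> np.ndarray:
    weights = 1.0 / np.arange(1, n + 1)
    return weights / weights.sum()


def generate_dataset(params: SynthParams) -> SynthDataset:
    """Generate the full dataset plus the injected-course ground truth."""
    rng = np.random.default_rng(params.seed)
    n_codes = params.n_medication_codes
    code_probs = _zipf_probs(n_codes)
    horizon = get_day_span(params.date_start, params.date_end)
    event_mean = params.event_mean

    summaries: list[SummaryRecord] = []
    events: list[EventRecord] = []
    courses: list[InjectedCourse] = []

    for p in range(params.n_patients):
        subject_id = f"P{p + 1:07d}"
        birth = add_day_span(
            dt.date(1925, 1, 1), int(rng.integers(0, 80 * 365))
        )
        n_adm = 1 + int(rng.poisson(params.mean_admissions_per_patient - 1.0))
        n_events_total = int(rng.poisson(event_mean))

        # split the patient's events across admissions
        if n_adm == 1:
            per_adm = [n_events_total]
        else:
            per_adm = list(rng.multinomial(
                n_events_total, np.full(n_adm, 1.0 / n_adm)
            ))

        adm_offsets = sorted(
            int(o) for o in rng.integers(0, max(1, horizon - 60), size=n_adm)
        )
        for a, (offset, n_ev) in enumerate(zip(adm_offsets, per_adm)):
            episode_id = f"E{p + 1:07d}_{a + 1}"
            admission = add_day_span(params.date_start, offset)
            los = max(1, int(round(rng.lognormal(mean=math.log(7.0), sigma=0.6))))
            discharge = add_day_span(admission, los)
            summaries.append(SummaryRecord(
                subject_id=subject_id,
                episode_id=episode_id,
                admission_date=admission,
                discharge_date=discharge,
                birth_date=birth,
                sex="F" if rng.random() < 0.5 else "M",
            ))

            n_course = 0
            if n_ev >= 3 and rng.random() < params.course_probability:
                n_course = int(min(n_ev, los + 1, rng.integers(3, 11)))
                course_code = _code(int(rng.choice(n_codes, p=code_probs)))
                start_off = int(rng.integers(0, los + 2 - n_course))
                course_start = add_day_span(admission, start_off)
                for d in range(n_course):
                    events.append(EventRecord(
                        subject_id=subject_id,
                        episode_id=episode_id,
                        event_date=add_day_span(course_start, d),
                        code=course_code,
                        quantity=1.0,
                    ))
                courses.append(InjectedCourse(
                    subject_id, episode_id, course_code, course_start, n_course
                ))

            for _ in range(n_ev - n_course):
                events.append(EventRecord(
                    subject_id=subject_id,
                    episode_id=episode_id,
                    event_date=add_day_span(admission, int(rng.integers(0, los + 1))),
                    code=_code(int(rng.choice(n_codes, p=code_probs))),
                    quantity=float(rng.integers(1, 4)),
                ))

    return SynthDataset(summaries=summaries, events=events,
                        courses=courses, params=params)


def generate(params: SynthParams) -> tuple[list[SummaryRecord], list[EventRecord]]:
    """Summaries and events only (see :func:`generate_dataset`)."""
    ds = generate_dataset(params)
    return ds.summaries, ds.events


def write_dataset(params: SynthParams, out_dir) -> dict[str, Path]:
    """Generate and write summary.tsv, events.tsv and catalog.gff.

    Deterministic: identical params yield byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(params)
    paths = {
        "summary": out / "summary.tsv",
        "events": out / "events.tsv",
        "catalog": out / "catalog.gff",
    }
    write_summaries(ds.summaries, paths["summary"])
    write_events(ds.events, paths["events"])
    write_gff(default_catalog(params), paths["catalog"])
    return paths
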