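import datetime as dt
import random

import pytest
from hypothesis import HealthCheck, settings

from widetab.gff import parse_gff
from widetab.records_io import EventRecord
from widetab.synth import SynthParams, generate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def abx_catalog():
    """The canonical two-group catalog used across unit tests."""
    return parse_gff("abx (c1 [100, 200], c2 [50, 75]), ppi (c3 [20, 30])")


@pytest.fixture
def shared_code_catalog():
    """A catalog where code "a" belongs to two groups with distinct values."""
    return parse_gff("g1 (a [1, 10]), g2 (a [2, 20], b [3, 30])")


def make_event(subject="P1", episode="E1", date=dt.date(2012, 1, 1),
               code="c1", quantity=1.0):
    return EventRecord(subject, episode, date, code, quantity)


@pytest.fixture
def make_events():
    """Factory: events from (code, day-offset) pairs for one subject."""

    def build(pairs, subject="P1", origin=dt.date(2012, 1, 1)):
        return [
            EventRecord(subject, "E1",
                        dt.date.fromordinal(origin.toordinal() + off),
                        code, 1.0)
            for code, off in pairs
        ]

    return build


@pytest.fixture(scope="session")
def desk_scale_dataset():
    """The 10,000-patient reference workload (≈ 4×10⁵ events), generated
    once per session and shared by the determinism and scaling tests."""
    return generate_dataset(SynthParams(n_patients=10_000, seed=20120151))


def random_instance(seed, max_events=200, max_groups=8):
    """One random pivot problem: catalog text, events, aggregation choices.

    Codes may belong to several groups; every item carries two values so
    any value index in {0, 1} is joinable.  Built with the stdlib random
    module only, independent of the package's generator.
    """
    rng = random.Random(seed)
    n_groups = rng.randint(1, max_groups)
    n_codes = rng.randint(1, 12)
    codes = [f"c{i}" for i in range(n_codes)]
    groups = []
    used = set()
    for g in range(n_groups):
        size = rng.randint(1, min(4, n_codes))
        members = rng.sample(codes, size)
        # quarter-unit values are exact binary fractions, so float sums are
        # order-independent and oracle comparison can demand exact equality
        items = {code: (rng.randint(1, 500), rng.randrange(4, 200) / 4)
                 for code in members}
        groups.append((f"grp{g}", items))
        used.update(members)
    group_text = ", ".join(
        f"{name} ({', '.join(f'{c} [{v[0]}, {v[1]}]' for c, v in items.items())})"
        for name, items in groups
    )
    n_events = rng.randint(0, max_events)
    subjects = [f"P{i}" for i in range(1, rng.randint(2, 6))]
    origin = dt.date(2012, 1, 1)
    all_codes = codes + ["zz1", "zz2"]  # some codes the catalog never defines
    events = [
        EventRecord(
            rng.choice(subjects),
            "E1",
            dt.date.fromordinal(origin.toordinal() + rng.randint(0, 60)),
            rng.choice(all_codes),
            float(rng.randint(1, 5)),
        )
        for _ in range(n_events)
    ]
    ops = ["COUNT", "SUM@0", "SUM@1", "MAX@0", "MIN@1", "SUM@qty",
           "FIRST_DATE", "LAST_DATE"]
    agg_text = ",".join(
        f"{name}={rng.choice(ops)}" for name, _ in groups
    )
    return group_text, groups, events, agg_text
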