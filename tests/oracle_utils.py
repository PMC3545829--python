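"""Independent brute-force oracles.

Everything here is deliberately naive — nested loops over plain tuples and
dicts, no streaming, no grouping machinery, no imports from the modules
under test beyond the record container — so agreement with the package is
evidence, not tautology.
"""

import datetime as dt


def oracle_membership_count(events, groups):
    """How many events have a code defined somewhere in the catalog."""
    defined = set()
    for _name, items in groups:
        defined.update(items)
    return sum(1 for e in events if e.code in defined)


def oracle_pivot(events, groups, agg_text):
    """Nested-loop long-to-wide pivot with aggregation.

    ``groups`` is [(name, {code: (v0, v1)}), ...]; ``agg_text`` is the
    same mini-syntax the package parses ("g=COUNT,g2=SUM@0,...").
    Returns {key: {group: scalar}} keyed by (subject_id, episode_id).
    """
    aggs = {}
    for clause in agg_text.split(","):
        if clause.strip():
            name, op = clause.split("=")
            aggs[name.strip()] = op.strip()

    keys = sorted({(e.subject_id, e.episode_id) for e in events
                   if any(e.code in items for _n, items in groups)})
    out = {}
    for key in keys:
        row = {}
        for name, items in groups:
            matched = [e for e in events
                       if (e.subject_id, e.episode_id) == key
                       and e.code in items]
            op = aggs.get(name, "COUNT")
            row[name] = _oracle_agg(matched, items, op)
        out[key] = row
    return out


def _oracle_agg(matched, items, op):
    if op == "COUNT":
        return len(matched)
    if op == "FIRST_DATE":
        return min((e.event_date for e in matched), default=None)
    if op == "LAST_DATE":
        return max((e.event_date for e in matched), default=None)
    base, _, src = op.partition("@")
    if src in ("qty", "quantity"):
        numbers = [e.quantity for e in matched]
    else:
        numbers = [items[e.code][int(src)] for e in matched]
    if base == "SUM":
        return float(sum(numbers))
    if not numbers:
        return None
    return float(max(numbers)) if base == "MAX" else float(min(numbers))


def oracle_day_span(d1, d2):
    """Day difference by brute-force single-day stepping (slow, exact)."""
    if d1 == d2:
        return 0
    step = dt.timedelta(days=1)
    n = 0
    if d2 > d1:
        cur = d1
        while cur != d2:
            cur += step
            n += 1
        return n
    cur = d2
    while cur != d1:
        cur += step
        n += 1
    return -n


def oracle_pickup(events, start, period_days, max_gap=0):
    """Scan offsets 0, 1, 2, ... while days keep having events."""
    covered = set()
    for e in events:
        off = (e.event_date - start).days
        if 0 <= off < period_days:
            covered.add(off)
    if 0 not in covered:
        return []
    last = 0
    gap = 0
    included_days = {0}
    for off in range(1, period_days):
        if off in covered:
            included_days.add(off)
            gap = 0
        else:
            gap += 1
            if gap > max_gap:
                break
    # days after the break are excluded even if covered
    max_day = max(included_days)
    return [e for e in events
            if 0 <= (e.event_date - start).days <= max_day]
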