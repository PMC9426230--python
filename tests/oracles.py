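"""Independent brute-force oracles for the course-assembly primitives.

These deliberately use the dumbest correct algorithms — exhaustive date
enumeration and pairwise transitive closure — so they share no code
path with the implementation they check.
"""

from __future__ import annotations

import pandas as pd


def lot_oracle(intervals) -> int:
    """Count calendar dates touched by half-open intervals by checking
    every date in the spanned range individually."""
    intervals = [(pd.Timestamp(s), pd.Timestamp(e)) for s, e in intervals]
    if not intervals:
        return 0
    lo = min(s for s, _ in intervals).normalize()
    hi = max(e for _, e in intervals).normalize()
    n = 0
    day = lo
    one_day = pd.Timedelta(days=1)
    while day <= hi:
        nxt = day + one_day
        for s, e in intervals:
            if s == e:
                covered = day <= s < nxt
            else:
                covered = s < nxt and e > day
            if covered:
                n += 1
                break
        day = nxt
    return n


def post_discharge_oracle(intervals, discharge) -> tuple[int, int]:
    """(inpatient, post) partition by per-date enumeration."""
    intervals = [(pd.Timestamp(s), pd.Timestamp(e)) for s, e in intervals]
    discharge_date = pd.Timestamp(discharge).normalize()
    lo = min(s for s, _ in intervals).normalize()
    hi = max(e for _, e in intervals).normalize()
    inpatient = post = 0
    day = lo
    one_day = pd.Timedelta(days=1)
    while day <= hi:
        nxt = day + one_day
        covered = any(
            (day <= s < nxt) if s == e else (s < nxt and e > day)
            for s, e in intervals
        )
        if covered:
            if day > discharge_date:
                post += 1
            else:
                inpatient += 1
        day = nxt
    return inpatient, post


def merge_oracle(orders: list[tuple[str, pd.Timestamp, pd.Timestamp]], gap_hours: float) -> list[frozenset]:
    """Episode partition by exhaustive pairwise closure.

    Two orders are linked when the later-starting one begins no more
    than ``gap_hours`` after the other's stop; linked sets are merged
    until a fixed point.
    """
    gap = pd.Timedelta(hours=gap_hours)

    def linked(a, b) -> bool:
        first, second = (a, b) if a[1] <= b[1] else (b, a)
        return second[1] <= first[2] + gap

    groups = [{i} for i in range(len(orders))]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if any(linked(orders[a], orders[b]) for a in groups[i] for b in groups[j]):
                    groups[i] |= groups[j]
                    del groups[j]
                    changed = True
                    break
            if changed:
                break
    return [frozenset(orders[i][0] for i in g) for g in groups]
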