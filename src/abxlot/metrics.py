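"""Length of therapy, post-discharge split, and duration adherence.

**LOT** (length of therapy) is the number of distinct calendar days on
which antimicrobials were consecutively prescribed for the definitive
indication, irrespective of the number of agents or doses on each day.
Operationally: the count of calendar dates intersected by the union of
the course's half-open order intervals.  Antibiotic-free days inside a
merged episode (possible with a 24-h gap tolerance) are *not* counted.

A covered calendar date counts as **post-discharge** when it is strictly
after the discharge calendar date — the discharge day itself is an
inpatient day.

A course is **adherent** when its LOT falls within the
guideline-recommended range, with a one-day margin on the upper bound:
calendar-day counting can only inflate LOT (a single evening dose adds
a full day), never deflate it, so the margin compensates upward only.
Courses for indications without an accepted guideline range, or with an
"other" code, are not assessable.
"""

from __future__ import annotations

from datetime import date, timedelta
from enum import Enum

import numpy as np
import pandas as pd

from .registry import GuidelineEntry, GuidelineTable, IndicationRegistry

__all__ = [
    "Adherence",
    "covered_dates",
    "compute_lot",
    "split_post_discharge",
    "assess_adherence",
    "course_metrics",
    "summarize_by_indication",
]

_ONE_MINUTE = pd.Timedelta(minutes=1)


class Adherence(str, Enum):
    ADHERENT = "adherent"
    TOO_LONG = "too_long"
    TOO_SHORT = "too_short"
    NOT_ASSESSABLE = "not_assessable"


def covered_dates(intervals) -> list[date]:
    """Sorted distinct calendar dates touched by half-open intervals.

    A degenerate interval (stop == start) covers its start date; an
    interval stopping exactly at midnight does not reach into the new
    day.  Timestamps carry minute resolution.
    """
    days: set[date] = set()
    for start, stop in intervals:
        start = pd.Timestamp(start)
        stop = pd.Timestamp(stop)
        if stop < start:
            raise ValueError("interval stop before start")
        last = start if stop == start else stop - _ONE_MINUTE
        d = start.date()
        end = last.date()
        while d <= end:
            days.add(d)
            d += timedelta(days=1)
    return sorted(days)


def compute_lot(intervals) -> int:
    """Calendar-day length of therapy of a course's member intervals."""
    return len(covered_dates(intervals))


def split_post_discharge(intervals, discharge: pd.Timestamp) -> tuple[int, int]:
    """Partition a course's LOT into (inpatient_days, post_discharge_days).

    A covered date is post-discharge iff strictly after the discharge
    calendar date; the two parts always sum to the LOT.
    """
    cutoff = pd.Timestamp(discharge).date()
    days = covered_dates(intervals)
    post = sum(1 for d in days if d > cutoff)
    return len(days) - post, post


def assess_adherence(
    lot_days: int,
    entry: GuidelineEntry | None,
    margin_days: int = 1,
) -> Adherence:
    """Classify a course's LOT against the guideline range.

    ``adherent`` iff ``min_days <= lot <= max_days + margin``; the
    margin applies to the upper bound only.  Without a guideline entry
    the course is not assessable.
    """
    if lot_days < 1:
        raise ValueError("LOT must be at least 1 day")
    if entry is None:
        return Adherence.NOT_ASSESSABLE
    if lot_days < entry.min_days:
        return Adherence.TOO_SHORT
    if lot_days > entry.max_days + margin_days:
        return Adherence.TOO_LONG
    return Adherence.ADHERENT


def course_metrics(
    courses: pd.DataFrame,
    orders: pd.DataFrame,
    admissions: pd.DataFrame,
    guidelines: GuidelineTable | None = None,
    registry: IndicationRegistry | None = None,
    margin_days: int = 1,
) -> pd.DataFrame:
    """Per-course metrics table for the analysis set.

    Joins each course's member orders and its admission, computes LOT,
    the inpatient/post-discharge partition and the adherence class of
    the definitive indication.
    """
    guidelines = guidelines or GuidelineTable.default()
    registry = registry or IndicationRegistry.default()
    by_order = orders.set_index("order_id")
    discharge_by_adm = admissions.set_index("admission_id")["discharge"]
    rows = []
    for c in courses.itertuples(index=False):
        member_ids = c.member_order_ids.split("|")
        members = by_order.loc[member_ids]
        intervals = list(zip(members["start"], members["stop"]))
        lot = compute_lot(intervals)
        inpatient_days, post_days = split_post_discharge(intervals, discharge_by_adm[c.admission_id])
        code = c.definitive_indication
        entry = guidelines.get(code) if guidelines.assessable(code, registry) else None
        rows.append({
            "course_id": c.course_id,
            "patient_id": c.patient_id,
            "admission_id": c.admission_id,
            "site": c.site,
            "indication_code": code,
            "lot_days": lot,
            "inpatient_days": inpatient_days,
            "post_discharge_days": post_days,
            "post_discharge_share": post_days / lot,
            "adherence": assess_adherence(lot, entry, margin_days=margin_days).value,
        })
    return pd.DataFrame(rows, columns=[
        "course_id", "patient_id", "admission_id", "site", "indication_code",
        "lot_days", "inpatient_days", "post_discharge_days",
        "post_discharge_share", "adherence",
    ])


def _summary_row(code: str, grp: pd.DataFrame, assessable: bool) -> dict:
    n = len(grp)
    post = grp[grp["post_discharge_days"] > 0]
    shares = post["post_discharge_share"].to_numpy(dtype=float) * 100.0
    lots = grp["lot_days"].to_numpy(dtype=float)
    row = {
        "indication_code": code,
        "n_courses": n,
        "n_post_discharge": len(post),
        "pct_post_discharge": 100.0 * len(post) / n,
        # averaged over courses with any post-discharge treatment only
        "mean_share_post_discharge": float(np.mean(shares)) if len(shares) else np.nan,
        "sd_share_post_discharge": float(np.std(shares, ddof=1)) if len(shares) > 1 else np.nan,
        "median_lot": float(np.quantile(lots, 0.5)),
        "q1_lot": float(np.quantile(lots, 0.25)),
        "q3_lot": float(np.quantile(lots, 0.75)),
        "pct_adherent": np.nan,
        "pct_too_long": np.nan,
    }
    if assessable:
        row["pct_adherent"] = 100.0 * (grp["adherence"] == Adherence.ADHERENT.value).mean()
        row["pct_too_long"] = 100.0 * (grp["adherence"] == Adherence.TOO_LONG.value).mean()
    return row


def summarize_by_indication(
    cm: pd.DataFrame,
    guidelines: GuidelineTable | None = None,
    registry: IndicationRegistry | None = None,
    min_courses: int = 20,
) -> pd.DataFrame:
    """Per-indication aggregate table plus a Total row.

    Indications observed in fewer than ``min_courses`` courses are
    pooled: their courses appear only in the Total row, their combined
    count in ``df.attrs["excluded_pool_n"]``.  Quantiles use linear
    interpolation between order statistics (recorded in
    ``df.attrs["quantile_method"]``).
    """
    guidelines = guidelines or GuidelineTable.default()
    registry = registry or IndicationRegistry.default()
    if cm.empty:
        out = pd.DataFrame(columns=[
            "indication_code", "n_courses", "n_post_discharge", "pct_post_discharge",
            "mean_share_post_discharge", "sd_share_post_discharge",
            "median_lot", "q1_lot", "q3_lot", "pct_adherent", "pct_too_long",
        ])
        out.attrs["excluded_pool_n"] = 0
        out.attrs["quantile_method"] = "linear"
        return out

    rows = []
    excluded_pool = 0
    excluded_codes = []
    for code in sorted(cm["indication_code"].unique()):
        grp = cm[cm["indication_code"] == code]
        if len(grp) < min_courses:
            excluded_pool += len(grp)
            excluded_codes.append(code)
            continue
        rows.append(_summary_row(code, grp, guidelines.assessable(code, registry)))
    rows.append(_summary_row("Total", cm, assessable=False))
    out = pd.DataFrame(rows)
    out.attrs["excluded_pool_n"] = excluded_pool
    out.attrs["excluded_codes"] = excluded_codes
    out.attrs["quantile_method"] = "linear"
    return out
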