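"""Assembly of treatment courses from individual prescription orders.

A *treatment course* is the unit of analysis: all consecutively
prescribed antibiotics of one patient around one admission, merged
across agent switches, combination therapy, discharge prescriptions and
outpatient prescriptions that continue the course.

Rules, in order:

1. **merge_consecutive** — orders of one admission form one episode when
   the later order starts no more than the gap tolerance (24 h by
   default) after the earlier order's stop, chained transitively;
   overlapping orders are always co-episode.
2. **link_outpatient** — outpatient orders starting within 24 h after
   the episode's last stop are appended (chained: each linked order
   extends the frontier) and inherit the definitive indication.
3. **keep_initial_episode** — when a patient received non-consecutive
   treatment during the admission, or was readmitted with antibiotics
   within 30 days of discharge, only the course of the initial episode
   is analysed; later episodes are logged and excluded.
4. **resolve_definitive_indication** — the indication registered last
   during the admission (registration clock = order start) holds for the
   whole course; two *different* indications registered simultaneously
   as the last registration disqualify the course.  Simultaneous orders
   sharing one indication are combination therapy, one course.
5. **apply_course_exclusions** — courses longer than 21 calendar days,
   courses for indications that in general need > 21 days (bone/joint
   infection, S. aureus bacteraemia, ...), prophylaxis, and
   dual-indication courses leave the analysis set, each removal logged.
"""

from __future__ import annotations

import pandas as pd

from .ingest import empty_log, _log_frame
from .metrics import compute_lot
from .registry import IndicationRegistry

__all__ = [
    "merge_consecutive",
    "link_outpatient",
    "keep_initial_episode",
    "resolve_definitive_indication",
    "apply_course_exclusions",
    "build_courses",
    "EXCLUSION_PRIORITY",
    "COURSE_COLUMNS",
]

GAP_HOURS_DEFAULT = 24.0
READMISSION_WINDOW_DAYS = 30
MAX_COURSE_DAYS = 21

EXCLUSION_PRIORITY = [
    "no_registered_indication",
    "dual_simultaneous_indication",
    "prophylaxis",
    "long_treatment_indication",
    "over_21_days",
]

COURSE_COLUMNS = [
    "course_id", "patient_id", "admission_id", "site", "episode_index",
    "member_order_ids", "course_start", "course_stop",
    "definitive_indication", "is_combination", "lot_days", "exclusion_flags",
]


def merge_consecutive(orders: pd.DataFrame, gap_hours: float = GAP_HOURS_DEFAULT) -> list[pd.DataFrame]:
    """Split one admission's orders into episodes of consecutive therapy.

    Orders are treated as half-open intervals; a single chronological
    sweep with a running stop-frontier is equivalent to the transitive
    closure of the pairwise gap condition.
    """
    if orders.empty:
        return []
    gap = pd.Timedelta(hours=gap_hours)
    sorted_orders = orders.sort_values(["start", "stop", "order_id"], kind="mergesort")
    episodes: list[list[int]] = []
    frontier: pd.Timestamp | None = None
    for idx, row in zip(sorted_orders.index, sorted_orders.itertuples(index=False)):
        if frontier is not None and row.start <= frontier + gap:
            episodes[-1].append(idx)
            frontier = max(frontier, row.stop)
        else:
            episodes.append([idx])
            frontier = row.stop
    return [sorted_orders.loc[ep] for ep in episodes]


def link_outpatient(
    episode: pd.DataFrame,
    outpatient_orders: pd.DataFrame,
    max_gap_hours: float = GAP_HOURS_DEFAULT,
) -> tuple[pd.DataFrame, list[str]]:
    """Append outpatient orders continuing an episode within 24 h.

    Linking is chained: a linked order pushes the stop frontier, so a
    later outpatient order within 24 h of the *new* frontier also links.
    Returns the extended episode and the linked order ids.  The episode
    never shortens: its stop is non-decreasing under linkage.
    """
    if episode.empty or outpatient_orders.empty:
        return episode, []
    gap = pd.Timedelta(hours=max_gap_hours)
    frontier = episode["stop"].max()
    first_start = episode["start"].min()
    linked: list[int] = []
    for row in outpatient_orders.sort_values(["start", "stop", "order_id"]).itertuples():
        if row.start < first_start:
            continue  # an outpatient order preceding the course is not part of it
        if row.start <= frontier + gap:
            linked.append(row.Index)
            frontier = max(frontier, row.stop)
    if not linked:
        return episode, []
    extended = pd.concat([episode, outpatient_orders.loc[linked]])
    return extended, list(outpatient_orders.loc[linked, "order_id"])


def resolve_definitive_indication(episode: pd.DataFrame) -> tuple[str | None, bool, bool]:
    """Return ``(indication, dual, is_combination)`` for one episode.

    The definitive indication is the one registered last during the
    admission, where the registration time of an indication is the start
    timestamp of the order carrying it.  Outpatient orders carry no
    registration.  A tie between two *different* codes at the latest
    registration time flags the course as dual-indication (excluded);
    simultaneous orders sharing one code are combination therapy.
    """
    bearing = episode[episode["setting"].isin(["inpatient", "discharge"])
                      & episode["indication_code"].notna()]
    if bearing.empty:
        return None, False, False
    t_last = bearing["start"].max()
    at_last = bearing[bearing["start"] == t_last]
    codes = set(at_last["indication_code"])
    dual = len(codes) > 1
    combo = bool(
        bearing.groupby(["start", "indication_code"], sort=False).size().gt(1).any()
    )
    indication = None if dual else codes.pop()
    return indication, dual, combo


def keep_initial_episode(
    courses: pd.DataFrame,
    admissions: pd.DataFrame,
    readmission_window_days: float = READMISSION_WINDOW_DAYS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep only each patient's initial course.

    Within an admission, episodes after the first are flagged
    ``non_initial_episode``.  Across admissions, a course in a
    readmission starting within 30 days (discharge-to-admission,
    inclusive) of the last analysed admission's discharge is flagged
    ``readmission_episode``; a later readmission becomes a fresh index.
    """
    window = pd.Timedelta(days=readmission_window_days)
    adm = admissions.set_index("admission_id")
    keep = pd.Series(True, index=courses.index)
    entries = []

    non_initial = courses["episode_index"] > 1
    for i in courses.index[non_initial]:
        keep[i] = False
        entries.append({"record_id": courses.at[i, "course_id"], "stage": "episode_selection",
                        "reason_code": "non_initial_episode",
                        "detail": f"episode {courses.at[i, 'episode_index']}"})

    initial = courses[~non_initial]
    for _, grp in initial.groupby("patient_id", sort=False):
        order = grp.assign(_admit=[adm.at[a, "admit"] for a in grp["admission_id"]]).sort_values("_admit")
        index_discharge = None
        for i, row in zip(order.index, order.itertuples(index=False)):
            admit = adm.at[row.admission_id, "admit"]
            if index_discharge is not None and admit - index_discharge <= window:
                keep[i] = False
                entries.append({"record_id": row.course_id, "stage": "episode_selection",
                                "reason_code": "readmission_episode",
                                "detail": f"readmitted {admit - index_discharge} after index discharge"})
            else:
                index_discharge = adm.at[row.admission_id, "discharge"]
    return courses[keep].copy(), _log_frame(entries)


def apply_course_exclusions(
    courses: pd.DataFrame,
    registry: IndicationRegistry,
    max_days: int = MAX_COURSE_DAYS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag and remove courses outside the analysable scope.

    The > 21-day rule applies to the merged course LOT (the unit of
    analysis), which also catches single orders longer than 21 days.
    Returns ``(analysis_courses, log)``; the log holds one row per
    removed course with the primary reason, all flags in the detail.
    """
    long_codes = set(registry.long_treatment_codes())
    keep = []
    entries = []
    for i, row in zip(courses.index, courses.itertuples(index=False)):
        flags = set(row.exclusion_flags.split(";")) if row.exclusion_flags else set()
        ind = row.definitive_indication
        if ind == "prophylaxis":
            flags.add("prophylaxis")
        if ind in long_codes:
            flags.add("long_treatment_indication")
        if row.lot_days > max_days:
            flags.add("over_21_days")
        courses.at[i, "exclusion_flags"] = ";".join(sorted(flags))
        if flags:
            keep.append(False)
            primary = next(f for f in EXCLUSION_PRIORITY if f in flags)
            entries.append({"record_id": row.course_id, "stage": "course_exclusions",
                            "reason_code": primary, "detail": ";".join(sorted(flags))})
        else:
            keep.append(True)
    return courses[pd.Series(keep, index=courses.index)].copy(), _log_frame(entries)


def build_courses(
    orders: pd.DataFrame,
    admissions: pd.DataFrame,
    decisions: pd.DataFrame,
    registry: IndicationRegistry | None = None,
    gap_hours: float = GAP_HOURS_DEFAULT,
    outpatient_gap_hours: float = GAP_HOURS_DEFAULT,
    readmission_window_days: float = READMISSION_WINDOW_DAYS,
    max_days: int = MAX_COURSE_DAYS,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the full course-assembly stage for included admissions.

    Returns ``(all_courses, analysis_courses, episode_log, exclusion_log)``.
    ``all_courses`` holds every assembled course (one row each, member
    order ids pipe-separated); ``analysis_courses`` the subset entering
    the metrics stage.  Deterministic: identical inputs yield identical
    tables.
    """
    registry = registry or IndicationRegistry.default()
    included = decisions[decisions["included"]]
    included_ids = set(included["admission_id"])
    adm_site = admissions.set_index("admission_id")["site"] if "site" in admissions.columns else None

    outpatient_pool = {
        pid: grp.copy()
        for pid, grp in orders[orders["setting"] == "outpatient"].groupby("patient_id", sort=False)
    }
    inpatient = orders[orders["admission_id"].notna() & orders["admission_id"].isin(included_ids)]

    rows = []
    adm_order = admissions.sort_values(["patient_id", "admit"])
    for adm in adm_order.itertuples(index=False):
        if adm.admission_id not in included_ids:
            continue
        adm_orders = inpatient[inpatient["admission_id"] == adm.admission_id]
        if adm_orders.empty:
            continue
        episodes = merge_consecutive(adm_orders, gap_hours=gap_hours)
        for epi_idx, episode in enumerate(episodes, start=1):
            pool = outpatient_pool.get(adm.patient_id)
            if pool is not None and not pool.empty:
                episode, linked_ids = link_outpatient(episode, pool, max_gap_hours=outpatient_gap_hours)
                if linked_ids:
                    outpatient_pool[adm.patient_id] = pool[~pool["order_id"].isin(linked_ids)]
            indication, dual, combo = resolve_definitive_indication(episode)
            flags = set()
            if indication is None and not dual:
                flags.add("no_registered_indication")
            if dual:
                flags.add("dual_simultaneous_indication")
            intervals = list(zip(episode["start"], episode["stop"]))
            rows.append({
                "course_id": f"{adm.admission_id}-E{epi_idx}",
                "patient_id": adm.patient_id,
                "admission_id": adm.admission_id,
                "site": adm_site[adm.admission_id] if adm_site is not None else "site_0",
                "episode_index": epi_idx,
                "member_order_ids": "|".join(episode.sort_values(["start", "order_id"])["order_id"]),
                "course_start": episode["start"].min(),
                "course_stop": episode["stop"].max(),
                "definitive_indication": indication,
                "is_combination": combo,
                "lot_days": compute_lot(intervals),
                "exclusion_flags": ";".join(sorted(flags)),
            })

    all_courses = pd.DataFrame(rows, columns=COURSE_COLUMNS)
    if all_courses.empty:
        return all_courses, all_courses.copy(), empty_log(), empty_log()

    initial, episode_log = keep_initial_episode(
        all_courses, admissions, readmission_window_days=readmission_window_days
    )
    analysis, exclusion_log = apply_course_exclusions(initial, registry, max_days=max_days)
    return all_courses, analysis, episode_log, exclusion_log
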