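"""Selection of the analysis cohort.

The surveillance targets adult patients admitted to a general ward who
received *empiric* systemic antibiotic treatment:

* hospitalized: admitted for at least 12 hours;
* empiric: an antibiotic order active at hour 24 of the admission, or —
  for stays of 12–24 hours — an order active at the discharge instant or
  issued with the discharge setting;
* adult (age >= 18) and not an Intensive Care admission, because
  guideline-recommended durations do not apply in those settings.

Order activity at an instant uses half-open intervals ``[start, stop)``
so abutting orders tile without double counting.  Every admission gets
exactly one decision with the full (possibly overlapping) set of
exclusion reasons.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "HOSPITALIZED_MIN",
    "EMPIRIC_INSTANT",
    "is_hospitalized",
    "is_empiric",
    "apply_patient_filters",
    "decide",
    "build_cohort",
    "REASON_PRIORITY",
]

HOSPITALIZED_MIN = pd.Timedelta(hours=12)
EMPIRIC_INSTANT = pd.Timedelta(hours=24)

#: order used to pick the single histogram reason for an excluded
#: admission when reasons overlap
REASON_PRIORITY = ["icu", "paediatric", "not_hospitalized_12h", "no_empiric_abx_24h"]


def is_hospitalized(admit: pd.Timestamp, discharge: pd.Timestamp) -> bool:
    """True iff the stay lasted at least 12 hours (boundary inclusive)."""
    return discharge - admit >= HOSPITALIZED_MIN


def _active_at(orders: pd.DataFrame, instant: pd.Timestamp) -> bool:
    if orders.empty:
        return False
    return bool(((orders["start"] <= instant) & (instant < orders["stop"])).any())


def is_empiric(admit: pd.Timestamp, discharge: pd.Timestamp, orders: pd.DataFrame) -> bool:
    """True iff treatment qualifies as empiric for this admission.

    ``orders`` are the admission's cleaned inpatient/discharge orders.
    Stays longer than 24 h: some order interval must cover the instant
    ``admit + 24 h``.  Stays of 12–24 h: some order must be active at the
    discharge instant, or be a discharge-setting prescription.
    """
    stay = discharge - admit
    if stay > EMPIRIC_INSTANT:
        return _active_at(orders, admit + EMPIRIC_INSTANT)
    if stay >= HOSPITALIZED_MIN:
        if _active_at(orders, discharge):
            return True
        return bool((orders["setting"] == "discharge").any()) if len(orders) else False
    return False


def apply_patient_filters(ward: str, age_years: int) -> set[str]:
    """Patient-level exclusions: paediatric (< 18 y) and ICU admissions."""
    reasons: set[str] = set()
    if age_years < 18:
        reasons.add("paediatric")
    if ward == "ICU":
        reasons.add("icu")
    return reasons


def decide(admission, orders: pd.DataFrame) -> set[str]:
    """All exclusion reasons for one admission; empty set means included."""
    reasons = apply_patient_filters(admission.ward, admission.age_years)
    if not is_hospitalized(admission.admit, admission.discharge):
        reasons.add("not_hospitalized_12h")
    if not is_empiric(admission.admit, admission.discharge, orders):
        reasons.add("no_empiric_abx_24h")
    return reasons


def build_cohort(admissions: pd.DataFrame, orders: pd.DataFrame) -> pd.DataFrame:
    """One CohortDecision row per admission.

    ``orders`` is the cleaned prescriptions table carrying an
    ``admission_id`` column (outpatient orders, which have none, never
    count towards the empiric check).
    """
    rows = []
    grouped = orders.groupby("admission_id", sort=False) if len(orders) else None
    for adm in admissions.itertuples(index=False):
        try:
            adm_orders = grouped.get_group(adm.admission_id) if grouped is not None else orders
        except KeyError:
            adm_orders = orders.iloc[0:0]
        reasons = decide(adm, adm_orders)
        rows.append({
            "admission_id": adm.admission_id,
            "patient_id": adm.patient_id,
            "included": not reasons,
            "reason_codes": ";".join(sorted(reasons)) if reasons else "included",
        })
    out = pd.DataFrame(rows, columns=["admission_id", "patient_id", "included", "reason_codes"])
    out["included"] = out["included"].astype(bool)
    return out


def primary_reason(reason_codes: str) -> str:
    """The single histogram reason for an excluded admission."""
    codes = set(reason_codes.split(";"))
    for r in REASON_PRIORITY:
        if r in codes:
            return r
    return reason_codes
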