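"""Reading, validation and cleaning of the two EMR extract tables.

The pipeline consumes two flat delimited tables:

* **prescriptions** — one row per antibiotic order: patient id, order id,
  ATC code, drug name, start/stop timestamps, setting (inpatient /
  discharge / outpatient), order status, registered indication code and
  prescriber specialty;
* **admissions** — one row per hospital stay: patient id, admission id,
  admit/discharge timestamps, ward type, age at admission and an
  optional site column.

Cleaning removes orders outside the configured ATC include list
(systemic antibacterials, class J01, by default), cancelled orders
(never administered) and erroneous orders whose start calendar date
falls before the calendar date of the admission they belong to.  Every
removed record is logged exactly once with a reason code so the
selection flow can be reported and audited.

Timestamps are timezone-naive local hospital time; the calendar-day
boundary is midnight.  Orders without a stop timestamp are truncated at
the dataset-extraction timestamp and flagged ``open_ended`` (a known
real-world error mode: prescriptions not terminated after discharge or
death); the truncation is logged as a warning, not a removal.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .registry import IndicationRegistry

__all__ = [
    "SchemaError",
    "ConsistencyError",
    "PRESCRIPTION_COLUMNS",
    "ADMISSION_COLUMNS",
    "read_prescriptions",
    "read_admissions",
    "parse_prescriptions",
    "parse_admissions",
    "filter_atc",
    "drop_cancelled",
    "drop_erroneous",
    "empty_log",
]

PRESCRIPTION_COLUMNS = [
    "patient_id", "order_id", "atc_code", "drug_name", "start", "stop",
    "setting", "status", "indication_code", "prescriber_specialty",
]
ADMISSION_COLUMNS = ["patient_id", "admission_id", "admit", "discharge", "ward", "age_years"]

SETTINGS = {"inpatient", "discharge", "outpatient"}
STATUSES = {"active", "completed", "cancelled"}
WARDS = {"general", "ICU"}

LOG_COLUMNS = ["record_id", "stage", "reason_code", "detail"]

#: grace window for joining discharge-setting orders written shortly
#: after the discharge event to the admission they belong to
DISCHARGE_JOIN_GRACE = pd.Timedelta(hours=24)


class SchemaError(ValueError):
    """The input table does not match the documented schema (fatal)."""


class ConsistencyError(ValueError):
    """The input violates a dataset-level invariant (fatal)."""


def empty_log() -> pd.DataFrame:
    return pd.DataFrame(columns=LOG_COLUMNS)


def _log_frame(entries: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(entries, columns=LOG_COLUMNS) if entries else empty_log()


def _normalise_columns(df: pd.DataFrame, required: list[str], table: str) -> pd.DataFrame:
    df = df.rename(columns={c: c.strip().lower() for c in df.columns})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}")
    return df


def _parse_ts(series: pd.Series) -> pd.Series:
    return pd.to_datetime(series, errors="coerce", format="ISO8601")


def parse_prescriptions(
    raw: pd.DataFrame,
    registry: IndicationRegistry | None = None,
    extraction_time: pd.Timestamp | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Validate a raw prescriptions table.

    Returns ``(orders, rejects, warnings)``: parsed orders, a log of
    rejected rows (one per removal) and a log of kept-but-flagged rows
    (open-ended stop truncated at ``extraction_time``).
    """
    registry = registry or IndicationRegistry.default()
    raw = _normalise_columns(raw.copy(), PRESCRIPTION_COLUMNS, "prescriptions")

    if raw.empty:
        orders = raw.assign(start=pd.Series(dtype="datetime64[ns]"),
                            stop=pd.Series(dtype="datetime64[ns]"),
                            open_ended=pd.Series(dtype=bool))
        return orders[PRESCRIPTION_COLUMNS + ["open_ended"]], empty_log(), empty_log()

    dup = raw["order_id"].duplicated()
    if dup.any():
        raise SchemaError(f"prescriptions: duplicate order_id(s) {sorted(raw.loc[dup, 'order_id'].unique())[:5]}")

    df = raw.copy()
    for col in ("setting", "status"):
        df[col] = df[col].astype(str).str.strip()
    start = _parse_ts(df["start"])
    stop_raw = df["stop"]
    stop_missing = stop_raw.isna() | (stop_raw.astype(str).str.strip() == "")
    stop = _parse_ts(stop_raw.where(~stop_missing))
    ind = df["indication_code"]
    ind_missing = ind.isna() | (ind.astype(str).str.strip() == "")
    ind = ind.astype(str).str.strip().where(~ind_missing)

    reason = pd.Series(index=df.index, dtype=object)

    def flag(mask: pd.Series, code: str) -> None:
        reason[reason.isna() & mask] = code

    flag(start.isna(), "unparseable_timestamp")
    flag(~stop_missing & stop.isna(), "unparseable_timestamp")
    flag(~df["setting"].isin(SETTINGS), "invalid_setting")
    flag(~df["status"].isin(STATUSES), "invalid_status")
    flag(stop.notna() & (stop < start), "negative_duration")
    flag(ind_missing & df["setting"].isin({"inpatient", "discharge"}), "missing_indication")
    flag(~ind_missing & ~ind.isin(registry.codes()), "unknown_indication")

    rejects = _log_frame([
        {"record_id": df.at[i, "order_id"], "stage": "parse_prescriptions",
         "reason_code": reason[i], "detail": f"row {i}"}
        for i in df.index[reason.notna()]
    ])

    kept = df[reason.isna()].copy()
    kept["start"] = start[reason.isna()]
    kept["stop"] = stop[reason.isna()]
    kept["indication_code"] = ind[reason.isna()]
    open_ended = kept["stop"].isna()
    if extraction_time is None:
        observed = pd.concat([kept["start"], kept["stop"]]).max()
        extraction_time = (observed + pd.Timedelta(days=1)) if pd.notna(observed) else pd.Timestamp.now()
    kept.loc[open_ended, "stop"] = pd.Timestamp(extraction_time)
    kept["open_ended"] = open_ended
    warnings = _log_frame([
        {"record_id": r, "stage": "parse_prescriptions", "reason_code": "open_ended",
         "detail": f"stop truncated at {extraction_time}"}
        for r in kept.loc[open_ended, "order_id"]
    ])
    return kept[PRESCRIPTION_COLUMNS + ["open_ended"]].reset_index(drop=True), rejects, warnings


def read_prescriptions(
    path: str | Path,
    registry: IndicationRegistry | None = None,
    delimiter: str = ",",
    extraction_time: pd.Timestamp | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read and validate a prescriptions file (UTF-8, ISO-8601 timestamps)."""
    raw = pd.read_csv(path, sep=delimiter, dtype=str)
    return parse_prescriptions(raw, registry=registry, extraction_time=extraction_time)


def parse_admissions(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate a raw admissions table; returns ``(admissions, rejects)``.

    Overlapping stays for one patient are a fatal consistency error.
    """
    raw = _normalise_columns(raw.copy(), ADMISSION_COLUMNS, "admissions")
    if "site" not in raw.columns:
        raw["site"] = "site_0"
    if raw.empty:
        adm = raw.assign(admit=pd.Series(dtype="datetime64[ns]"),
                         discharge=pd.Series(dtype="datetime64[ns]"),
                         age_years=pd.Series(dtype=int))
        return adm[ADMISSION_COLUMNS + ["site"]], empty_log()

    dup = raw["admission_id"].duplicated()
    if dup.any():
        raise SchemaError("admissions: duplicate admission_id(s)")

    df = raw.copy()
    admit = _parse_ts(df["admit"])
    discharge = _parse_ts(df["discharge"])
    age = pd.to_numeric(df["age_years"], errors="coerce")
    df["ward"] = df["ward"].astype(str).str.strip()

    reason = pd.Series(index=df.index, dtype=object)

    def flag(mask: pd.Series, code: str) -> None:
        reason[reason.isna() & mask] = code

    flag(admit.isna() | discharge.isna(), "unparseable_timestamp")
    flag(discharge.notna() & admit.notna() & (discharge <= admit), "nonpositive_stay")
    flag(~df["ward"].isin(WARDS), "invalid_ward")
    flag(age.isna() | (age < 0) | (age % 1 != 0), "invalid_age")

    rejects = _log_frame([
        {"record_id": df.at[i, "admission_id"], "stage": "parse_admissions",
         "reason_code": reason[i], "detail": f"row {i}"}
        for i in df.index[reason.notna()]
    ])
    kept = df[reason.isna()].copy()
    kept["admit"] = admit[reason.isna()]
    kept["discharge"] = discharge[reason.isna()]
    kept["age_years"] = age[reason.isna()].astype(int)
    kept = kept[ADMISSION_COLUMNS + ["site"]].reset_index(drop=True)

    for pid, grp in kept.groupby("patient_id", sort=False):
        g = grp.sort_values("admit")
        if (g["admit"].iloc[1:].values < g["discharge"].iloc[:-1].values).any():
            raise ConsistencyError(f"admissions: overlapping stays for patient {pid}")
    return kept, rejects


def read_admissions(path: str | Path, delimiter: str = ",") -> tuple[pd.DataFrame, pd.DataFrame]:
    raw = pd.read_csv(path, sep=delimiter, dtype=str)
    return parse_admissions(raw)


def filter_atc(
    orders: pd.DataFrame, include_prefixes: tuple[str, ...] = ("J01",)
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep orders whose ATC code matches at least one configured prefix."""
    if not include_prefixes:
        raise ValueError("include_prefixes must be non-empty")
    codes = orders["atc_code"].astype(str)
    keep = codes.str.startswith(tuple(include_prefixes))
    log = _log_frame([
        {"record_id": r.order_id, "stage": "atc_filter", "reason_code": "non_included_atc",
         "detail": r.atc_code}
        for r in orders[~keep].itertuples(index=False)
    ])
    return orders[keep].reset_index(drop=True), log


def drop_cancelled(orders: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove orders labelled cancelled — these were never administered."""
    cancelled = orders["status"] == "cancelled" if len(orders) else pd.Series(dtype=bool)
    log = _log_frame([
        {"record_id": r, "stage": "drop_cancelled", "reason_code": "cancelled", "detail": ""}
        for r in orders.loc[cancelled, "order_id"]
    ] if len(orders) else [])
    return orders[~cancelled].reset_index(drop=True) if len(orders) else orders.copy(), log


def _join_admission(order, admissions_by_patient: dict) -> tuple[str | None, str | None]:
    """Attribute one inpatient/discharge order to an admission.

    Returns ``(admission_id, reason)`` where reason is None when joined,
    ``erroneous_pre_admission`` when the start calendar date precedes the
    admission calendar date, or ``orphan_order`` when no admission fits.
    """
    adms = admissions_by_patient.get(order.patient_id)
    if adms is None:
        return None, "orphan_order"
    start = order.start
    for a in adms:  # sorted by admit; stays are disjoint
        if a.admit <= start <= a.discharge:
            return a.admission_id, None
    if order.setting == "discharge":
        for a in adms:
            if a.discharge < start <= a.discharge + DISCHARGE_JOIN_GRACE:
                return a.admission_id, None
    for a in adms:
        if a.admit > start:
            if start.normalize() < a.admit.normalize():
                return None, "erroneous_pre_admission"
            return a.admission_id, None  # same calendar date, shortly before admit
    return None, "orphan_order"


def drop_erroneous(
    orders: pd.DataFrame, admissions: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove erroneous inpatient/discharge orders and attribute the rest.

    An order is erroneous when its start calendar **date** falls before
    the calendar date of the admission it belongs to (data-entry error:
    the drug cannot have been given before the patient was there).  The
    boundary is inclusive: an order starting exactly at the admit
    timestamp, or earlier the same calendar day, is kept.  Kept orders
    gain an ``admission_id`` column (missing for outpatient orders, which
    are linked to courses later via the 24-h rule).
    """
    by_patient = {
        pid: list(grp.sort_values("admit").itertuples(index=False))
        for pid, grp in admissions.groupby("patient_id", sort=False)
    }
    keep_mask = np.ones(len(orders), dtype=bool)
    adm_ids: list[str | None] = []
    entries = []
    for pos, order in enumerate(orders.itertuples(index=False)):
        if order.setting == "outpatient":
            adm_ids.append(None)
            continue
        adm_id, reason = _join_admission(order, by_patient)
        if reason is None:
            adm_ids.append(adm_id)
        else:
            keep_mask[pos] = False
            entries.append({"record_id": order.order_id, "stage": "drop_erroneous",
                            "reason_code": reason, "detail": str(order.start)})
    kept = orders[keep_mask].copy()
    kept["admission_id"] = adm_ids  # one entry per kept order, in order
    return kept.reset_index(drop=True), _log_frame(entries)
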