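"""Synthetic EMR generator with ground truth.

The real inputs of this pipeline are pseudonymised hospital EMR
extracts that cannot be redistributed, so every stage is tested against
simulated prescription/admission tables instead.  The generator is
*course-first*: for each patient it draws the truth (indication, total
calendar-day LOT, post-discharge split, cohort membership) and only then
fragments the course into prescription orders and injects the error
modes observed during real-world validation — cancelled orders, orders
starting before the admission date, post-discharge (OPAT) tails that
never reached the electronic system, mis-registered indications, and
never-terminated open-ended orders.  Ground truth is therefore well
defined by construction and the pipeline's reconstruction can be scored
against it.

Default parameters are shipped in ``data/indication_params.csv``
(per-indication case mix, LOT medians, post-discharge probabilities and
shares) and in the :class:`SimConfig` defaults; they emulate the
surveillance setting of a two-site tertiary-care centre and are
defaults, not assertions about any real hospital.  The generator models
only the time/indication structure the analysis consumes — not drug
choice, dosing or microbiology.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from . import metrics
from .ingest import ADMISSION_COLUMNS, PRESCRIPTION_COLUMNS
from .registry import GuidelineTable, IndicationRegistry, packaged_data_path

__all__ = ["SimConfig", "SimResult", "simulate", "make_fixture", "annotations_from_truth", "FIXTURE_NAMES"]

_DRUGS = [
    ("J01CA04", "amoxicillin"),
    ("J01CR02", "amoxicillin/clavulanate"),
    ("J01DD04", "ceftriaxone"),
    ("J01MA02", "ciprofloxacin"),
    ("J01XE01", "nitrofurantoin"),
    ("J01FA09", "clarithromycin"),
    ("J01DC02", "cefuroxime"),
    ("J01GB03", "gentamicin"),
]

#: indication pairs prescribers confuse most often at order entry
_CONFUSABLE = {
    "UTI-cystitis": "UTI-complicated",
    "UTI-complicated": "UTI-cystitis",
    "RTI-CAP_severe": "RTI-CAP_mild_moderate",
    "RTI-CAP_mild_moderate": "RTI-CAP_severe",
    "gastroenteritis": "intraabdominal",
    "intraabdominal": "gastroenteritis",
}

_ERROR_MODES = ("cancelled", "pre_admission_start", "missing_opat_tail", "wrong_indication", "open_ended")


def _load_params() -> pd.DataFrame:
    return pd.read_csv(packaged_data_path("indication_params.csv")).set_index("code")


class SimConfig(BaseModel):
    """Parameters of the synthetic two-site EMR."""

    n_patients: int = Field(default=1000, gt=0)
    seed: int = 0
    study_start: pd.Timestamp = pd.Timestamp("2020-06-01")
    study_end: pd.Timestamp = pd.Timestamp("2021-12-31")
    site_weights: dict[str, float] = Field(default_factory=lambda: {"site_a": 0.5, "site_b": 0.5})
    # per-indication overrides; None -> packaged defaults
    indication_distribution: dict[str, float] | None = None
    lot_family: str = "lognormal"
    lot_medians: dict[str, float] | None = None
    lot_dispersion: dict[str, float] | None = None
    p_post_discharge: dict[str, float] | None = None
    target_share_post_discharge: dict[str, float] | None = None
    share_sd: dict[str, float] | None = None
    p_fragmentation: float = 0.35
    p_combination: float = 0.10
    error_rates: dict[str, float] = Field(default_factory=lambda: {
        "cancelled": 0.08,
        "pre_admission_start": 0.05,
        "missing_opat_tail": 0.045,
        "wrong_indication": 0.17,
        "open_ended": 0.005,
    })
    p_icu: float = 0.10
    p_paediatric: float = 0.10
    p_prophylaxis: float = 0.04
    p_dual_indication: float = 0.01
    p_long_indication: float = 0.03
    p_readmission_30d: float = 0.05

    model_config = {"arbitrary_types_allowed": True}

    @field_validator(
        "p_fragmentation", "p_combination", "p_icu", "p_paediatric",
        "p_prophylaxis", "p_dual_indication", "p_long_indication", "p_readmission_30d",
    )
    @classmethod
    def _prob(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("probability outside [0, 1]")
        return v

    @field_validator("error_rates")
    @classmethod
    def _rates(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(_ERROR_MODES)
        if unknown:
            raise ValueError(f"unknown error mode(s): {sorted(unknown)}")
        full = {m: 0.0 for m in _ERROR_MODES}
        full.update(v)
        if any(not 0.0 <= r <= 1.0 for r in full.values()):
            raise ValueError("error rate outside [0, 1]")
        return full

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if self.indication_distribution is not None:
            total = sum(self.indication_distribution.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"indication_distribution sums to {total}, not 1")
        if self.lot_family not in {"lognormal", "gamma"}:
            raise ValueError("lot_family must be lognormal or gamma")
        if self.study_end <= self.study_start:
            raise ValueError("study_end must be after study_start")
        return self

    @classmethod
    def noiseless(cls, **kwargs) -> "SimConfig":
        """All error modes off; structural features untouched."""
        kwargs.setdefault("error_rates", {m: 0.0 for m in _ERROR_MODES})
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    @property
    def extraction_time(self) -> pd.Timestamp:
        """Timestamp at which the dataset was "extracted" — open-ended
        orders are truncated here."""
        return self.study_end + pd.Timedelta(days=1)


@dataclass
class SimResult:
    prescriptions: pd.DataFrame
    admissions: pd.DataFrame
    ground_truth: pd.DataFrame
    extraction_time: pd.Timestamp
    config: SimConfig

    def to_csv_dir(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.prescriptions.to_csv(out / "prescriptions.csv", index=False)
        self.admissions.to_csv(out / "admissions.csv", index=False)
        self.ground_truth.to_csv(out / "ground_truth.csv", index=False)


class _IdGen:
    def __init__(self) -> None:
        self.n_order = 0
        self.n_adm = 0

    def order(self) -> str:
        self.n_order += 1
        return f"O{self.n_order:06d}"

    def adm(self) -> str:
        self.n_adm += 1
        return f"A{self.n_adm:05d}"


def _round_lot(rng: np.random.Generator, family: str, median: float, sigma: float) -> int:
    if family == "lognormal":
        draw = float(np.exp(rng.normal(np.log(median), sigma)))
    else:  # gamma with the requested median, shape from dispersion
        shape = 1.0 / (sigma**2)
        draw = float(rng.gamma(shape, median / max(shape - 1.0 / 3.0, 0.5)))
    return max(1, int(round(draw)))


def simulate(config: SimConfig) -> SimResult:
    """Generate admissions, prescriptions and ground truth.

    Deterministic under a fixed ``config.seed``; every schema invariant
    of the ingest stage holds except where an error mode is deliberately
    injected, and every injection is labelled in the ground truth.
    """
    rng = np.random.default_rng(config.seed)
    registry = IndicationRegistry.default()
    guidelines = GuidelineTable.default()
    params = _load_params()

    normal_codes = [c for c in params.index if params.at[c, "weight"] > 0]
    if config.indication_distribution is not None:
        dist_codes = list(config.indication_distribution)
        dist_p = np.array([config.indication_distribution[c] for c in dist_codes])
        unknown = [c for c in dist_codes if c not in registry]
        if unknown:
            raise ValueError(f"indication_distribution has unknown code(s): {unknown}")
    else:
        dist_codes = normal_codes
        w = params.loc[dist_codes, "weight"].to_numpy(dtype=float)
        dist_p = w / w.sum()
    long_codes = registry.long_treatment_codes()
    sites = sorted(config.site_weights)
    site_p = np.array([config.site_weights[s] for s in sites], dtype=float)
    site_p = site_p / site_p.sum()

    def param(table: dict | None, code: str, column: str) -> float:
        if table is not None and code in table:
            return float(table[code])
        return float(params.at[code, column])

    horizon = max((config.study_end - config.study_start).days - 45, 1)
    ids = _IdGen()
    presc_rows: list[dict] = []
    adm_rows: list[dict] = []
    gt_rows: list[dict] = []

    def emit_order(pid, start, stop, setting, status, indication, open_end=False):
        atc, drug = _DRUGS[int(rng.integers(0, len(_DRUGS)))]
        row = {
            "patient_id": pid, "order_id": ids.order(), "atc_code": atc, "drug_name": drug,
            "start": start, "stop": pd.NaT if open_end else stop,
            "setting": setting, "status": status,
            "indication_code": indication, "prescriber_specialty": "internal_medicine",
        }
        presc_rows.append(row)
        return row

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        site = sites[int(rng.choice(len(sites), p=site_p))]

        u_cat = rng.random()
        if u_cat < config.p_icu:
            category = "icu"
        elif u_cat < config.p_icu + config.p_paediatric:
            category = "paediatric"
        else:
            category = "general"
        age = int(rng.integers(1, 18)) if category == "paediatric" else int(rng.integers(18, 96))
        ward = "ICU" if category == "icu" else "general"

        u_special = rng.random()
        if u_special < config.p_dual_indication:
            special = "dual"
        elif u_special < config.p_dual_indication + config.p_prophylaxis:
            special = "prophylaxis"
        elif u_special < config.p_dual_indication + config.p_prophylaxis + config.p_long_indication:
            special = "long"
        else:
            special = "normal"

        if special == "prophylaxis":
            true_ind = "prophylaxis"
        elif special == "long":
            true_ind = long_codes[int(rng.integers(0, len(long_codes)))]
        else:
            true_ind = dist_codes[int(rng.choice(len(dist_codes), p=dist_p))]
        second_ind = None
        if special == "dual":
            others = [c for c in normal_codes if c != true_ind]
            second_ind = others[int(rng.integers(0, len(others)))]

        L = _round_lot(
            rng, config.lot_family,
            param(config.lot_medians, true_ind, "median_lot_days"),
            param(config.lot_dispersion, true_ind, "lot_sigma"),
        )

        rates = config.error_rates
        err_cancelled = rng.random() < rates["cancelled"]
        err_pre = rng.random() < rates["pre_admission_start"]
        err_opat = rng.random() < rates["missing_opat_tail"] and special != "dual"
        err_wrong = rng.random() < rates["wrong_indication"] and special == "normal"
        err_open = rng.random() < rates["open_ended"]

        if err_wrong:
            registered = _CONFUSABLE.get(true_ind)
            if registered is None:
                others = [c for c in normal_codes if c != true_ind]
                registered = others[int(rng.integers(0, len(others)))]
        else:
            registered = true_ind

        # post-discharge split; the un-captured OPAT error mode implies a tail
        if err_opat:
            L = max(L, 2)
            post = True
        elif special == "dual":
            post = False
        else:
            post = rng.random() < param(config.p_post_discharge, true_ind, "p_post_discharge")
        if post and L >= 2:
            share = float(np.clip(
                rng.normal(param(config.target_share_post_discharge, true_ind, "share_post_discharge"),
                           param(config.share_sd, true_ind, "share_sd")),
                0.1, 0.9,
            ))
            P = min(max(1, int(round(share * L))), L - 1)
        else:
            post = False
            P = 0
        I = L - P

        day0 = (config.study_start + pd.Timedelta(days=int(rng.integers(0, horizon)))).normalize()
        minute = int(rng.integers(0, 4)) * 15
        if I == 1:
            admit = day0 + pd.Timedelta(hours=int(rng.integers(0, 9)), minutes=minute)
            discharge = admit + pd.Timedelta(hours=13, minutes=int(rng.integers(0, 90)))
        else:
            admit = day0 + pd.Timedelta(hours=int(rng.integers(6, 19)), minutes=minute)
            discharge = day0 + pd.Timedelta(days=I - 1, hours=int(rng.integers(11, 18)))
        course_start = admit + pd.Timedelta(hours=int(rng.integers(1, 5)), minutes=int(rng.integers(0, 60)))
        if L == 1 and P == 0 and I == 1:
            course_stop = discharge + pd.Timedelta(minutes=30)
        else:
            course_stop = day0 + pd.Timedelta(days=L - 1, hours=20, minutes=int(rng.integers(0, 120)))

        adm_id = ids.adm()
        adm_rows.append({"patient_id": pid, "admission_id": adm_id, "admit": admit,
                         "discharge": discharge, "ward": ward, "age_years": age, "site": site})

        # the last inpatient administration runs a few minutes past the
        # discharge timestamp, so the course is active at the discharge
        # instant even when the post-discharge tail goes un-captured
        inpatient_end = (discharge + pd.Timedelta(minutes=15)) if P > 0 else course_stop
        # fragmentation: agent switch splits the inpatient span into abutting orders
        segments: list[tuple[pd.Timestamp, pd.Timestamp, str]] = []
        span = inpatient_end - course_start
        fragged = rng.random() < config.p_fragmentation and span >= pd.Timedelta(hours=6)
        if fragged:
            cut = course_start + span * float(rng.uniform(0.3, 0.7))
            cut = cut.floor("min")
            first_ind = registered
            if special == "normal" and registered != "sepsis_unknown" and rng.random() < 0.5:
                # empiric start under a broad working diagnosis, refined later
                first_ind = "sepsis_unknown"
            segments.append((course_start, cut, first_ind))
            segments.append((cut, inpatient_end, registered))
        else:
            segments.append((course_start, inpatient_end, registered))

        emitted_course: list[tuple[pd.Timestamp, pd.Timestamp]] = []
        for s_start, s_stop, s_ind in segments:
            emit_order(pid, s_start, s_stop, "inpatient", "completed", s_ind)
            emitted_course.append((s_start, s_stop))
        if rng.random() < config.p_combination:
            s_start, s_stop, s_ind = segments[0]
            emit_order(pid, s_start, s_stop, "inpatient", "completed", s_ind)
            emitted_course.append((s_start, s_stop))
        if special == "dual":
            s_start, s_stop, _ = segments[-1]
            emit_order(pid, s_start, s_stop, "inpatient", "completed", second_ind)
            emitted_course.append((s_start, s_stop))

        true_course = list(emitted_course)
        if P > 0:
            if rng.random() < 0.25:
                tail_start = discharge + pd.Timedelta(hours=int(rng.integers(1, 13)))
                tail = (tail_start, course_stop, "outpatient", None)
            else:
                tail = (discharge, course_stop, "discharge", registered)
            true_course.append((tail[0], tail[1]))
            if not err_opat:
                emit_order(pid, tail[0], tail[1], tail[2], "completed", tail[3])
                emitted_course.append((tail[0], tail[1]))

        if err_open and emitted_course:
            # the chronologically last emitted order of this course loses its stop
            last = max(range(len(emitted_course)), key=lambda k: emitted_course[k][1])
            # find the matching prescription row (last appended with that interval)
            for row in reversed(presc_rows):
                if (row["patient_id"] == pid and row["start"] == emitted_course[last][0]
                        and row["stop"] == emitted_course[last][1]):
                    row["stop"] = pd.NaT
                    break
            emitted_course[last] = (emitted_course[last][0], config.extraction_time)

        if err_cancelled:
            emit_order(pid, admit + pd.Timedelta(hours=2), admit + pd.Timedelta(hours=26),
                       "inpatient", "cancelled", registered)
        if err_pre:
            pre_start = admit - pd.Timedelta(days=int(rng.integers(1, 4)))
            emit_order(pid, pre_start, pre_start + pd.Timedelta(hours=24),
                       "inpatient", "completed", registered)

        emitted_lot = metrics.compute_lot(emitted_course)
        _, emitted_post = metrics.split_post_discharge(emitted_course, discharge)

        if category != "general":
            cohort_reason = "icu" if category == "icu" else "paediatric"
            exclusion = ""
        else:
            cohort_reason = "included"
            if special == "dual":
                exclusion = "dual_simultaneous_indication"
            elif special == "prophylaxis":
                exclusion = "prophylaxis"
            elif special == "long":
                exclusion = "long_treatment_indication"
            elif emitted_lot > 21:
                exclusion = "over_21_days"
            else:
                exclusion = ""

        entry = guidelines.get(registered) if guidelines.assessable(registered, registry) else None
        gt_rows.append({
            "patient_id": pid, "admission_id": adm_id, "course_id": f"{adm_id}-E1", "site": site,
            "true_indication": true_ind, "registered_indication": registered,
            "true_lot": L, "true_post_discharge_days": P,
            "emitted_lot": emitted_lot, "emitted_post_discharge_days": emitted_post,
            "expected_adherence": metrics.assess_adherence(emitted_lot, entry).value,
            "cohort_reason": cohort_reason, "exclusion_reason": exclusion,
            "error_cancelled": err_cancelled, "error_pre_admission": err_pre,
            "error_missing_opat_tail": err_opat and P > 0,
            "error_wrong_indication": err_wrong, "error_open_ended": err_open,
        })

        # 30-day readmission with a fresh antibiotic episode (excluded downstream)
        if category == "general" and rng.random() < config.p_readmission_30d:
            d = int(rng.integers(2, 29))
            admit2 = discharge.normalize() + pd.Timedelta(days=d, hours=10)
            L2 = int(rng.integers(2, 8))
            discharge2 = admit2.normalize() + pd.Timedelta(days=L2 - 1, hours=15)
            start2 = admit2 + pd.Timedelta(hours=2)
            stop2 = admit2.normalize() + pd.Timedelta(days=L2 - 1, hours=20)
            ind2 = dist_codes[int(rng.choice(len(dist_codes), p=dist_p))]
            adm2_id = ids.adm()
            adm_rows.append({"patient_id": pid, "admission_id": adm2_id, "admit": admit2,
                             "discharge": discharge2, "ward": "general", "age_years": age, "site": site})
            emit_order(pid, start2, stop2, "inpatient", "completed", ind2)
            entry2 = guidelines.get(ind2) if guidelines.assessable(ind2, registry) else None
            gt_rows.append({
                "patient_id": pid, "admission_id": adm2_id, "course_id": f"{adm2_id}-E1", "site": site,
                "true_indication": ind2, "registered_indication": ind2,
                "true_lot": L2, "true_post_discharge_days": 0,
                "emitted_lot": L2, "emitted_post_discharge_days": 0,
                "expected_adherence": metrics.assess_adherence(L2, entry2).value,
                "cohort_reason": "included", "exclusion_reason": "readmission_episode",
                "error_cancelled": False, "error_pre_admission": False,
                "error_missing_opat_tail": False,
                "error_wrong_indication": False, "error_open_ended": False,
            })

    prescriptions = pd.DataFrame(presc_rows, columns=PRESCRIPTION_COLUMNS)
    admissions = pd.DataFrame(adm_rows, columns=ADMISSION_COLUMNS + ["site"])
    ground_truth = pd.DataFrame(gt_rows)
    return SimResult(prescriptions, admissions, ground_truth, config.extraction_time, config)


def annotations_from_truth(sample: pd.DataFrame, ground_truth: pd.DataFrame) -> pd.DataFrame:
    """Build the chart-review annotation file a human reviewer would
    produce, from the generator's ground truth: the chart holds the true
    LOT and true indication of each sampled course."""
    gt = ground_truth.set_index("course_id")
    return pd.DataFrame({
        "course_id": sample["course_id"].to_numpy(),
        "chart_lot_days": [gt.at[c, "true_lot"] for c in sample["course_id"]],
        "chart_indication": [gt.at[c, "true_indication"] for c in sample["course_id"]],
    })


# ---------------------------------------------------------------------------
# hand-constructed boundary fixtures


@dataclass
class Fixture:
    name: str
    prescriptions: pd.DataFrame
    admissions: pd.DataFrame
    expected: dict


def _presc(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=PRESCRIPTION_COLUMNS)
    return df


def _adm(rows: list[dict]) -> pd.DataFrame:
    for r in rows:
        r.setdefault("site", "site_0")
    return pd.DataFrame(rows, columns=ADMISSION_COLUMNS + ["site"])


def _o(pid, oid, start, stop, setting="inpatient", status="completed",
       ind="UTI-cystitis", atc="J01CA04", drug="amoxicillin"):
    return {"patient_id": pid, "order_id": oid, "atc_code": atc, "drug_name": drug,
            "start": pd.Timestamp(start), "stop": pd.Timestamp(stop) if stop is not None else pd.NaT,
            "setting": setting, "status": status, "indication_code": ind,
            "prescriber_specialty": "internal_medicine"}


def _a(pid, aid, admit, discharge, ward="general", age=50):
    return {"patient_id": pid, "admission_id": aid, "admit": pd.Timestamp(admit),
            "discharge": pd.Timestamp(discharge), "ward": ward, "age_years": age}


def _fixtures() -> dict[str, Fixture]:
    f: dict[str, Fixture] = {}

    f["evening_dose"] = Fixture(
        "evening_dose",
        _presc([
            _o("F1", "F1O1", "2021-03-01 22:00", "2021-03-01 23:00", setting="discharge"),
            _o("F2", "F2O1", "2021-03-01 22:00", "2021-03-02 02:00", setting="discharge"),
        ]),
        _adm([
            _a("F1", "FA1", "2021-03-01 05:00", "2021-03-01 18:00"),
            _a("F2", "FA2", "2021-03-01 05:00", "2021-03-01 18:00"),
        ]),
        {"lot": {"F1": 1, "F2": 2}},
    )

    f["gap_boundary"] = Fixture(
        "gap_boundary",
        _presc([
            _o("G1", "G1O1", "2021-03-01 08:00", "2021-03-02 08:00"),
            _o("G1", "G1O2", "2021-03-03 08:00", "2021-03-04 08:00"),
            _o("G2", "G2O1", "2021-03-01 08:00", "2021-03-02 08:00"),
            _o("G2", "G2O2", "2021-03-03 08:01", "2021-03-04 08:00"),
        ]),
        _adm([
            _a("G1", "GA1", "2021-03-01 07:00", "2021-03-10 12:00"),
            _a("G2", "GA2", "2021-03-01 07:00", "2021-03-10 12:00"),
        ]),
        {"episodes": {"G1": 1, "G2": 2}, "lot": {"G1": 4, "G2": 2}},
    )

    f["outpatient_link_boundary"] = Fixture(
        "outpatient_link_boundary",
        _presc([
            _o("H1", "H1O1", "2021-03-01 08:00", "2021-03-03 12:00"),
            _o("H1", "H1O2", "2021-03-04 12:00", "2021-03-06 10:00", setting="outpatient", ind=None),
            _o("H2", "H2O1", "2021-03-01 08:00", "2021-03-03 12:00"),
            _o("H2", "H2O2", "2021-03-04 12:01", "2021-03-06 10:00", setting="outpatient", ind=None),
        ]),
        _adm([
            _a("H1", "HA1", "2021-03-01 07:00", "2021-03-03 12:00"),
            _a("H2", "HA2", "2021-03-01 07:00", "2021-03-03 12:00"),
        ]),
        {"lot": {"H1": 6, "H2": 3}, "post": {"H1": 3, "H2": 0}},
    )

    f["readmission_boundary"] = Fixture(
        "readmission_boundary",
        _presc([
            _o("R1", "R1O1", "2021-03-01 09:00", "2021-03-03 10:00"),
            _o("R1", "R1O2", "2021-04-02 13:00", "2021-04-04 10:00"),
            _o("R2", "R2O1", "2021-03-01 09:00", "2021-03-03 10:00"),
            _o("R2", "R2O2", "2021-04-03 13:00", "2021-04-05 10:00"),
        ]),
        _adm([
            _a("R1", "RA1", "2021-03-01 08:00", "2021-03-03 12:00"),
            _a("R1", "RA2", "2021-04-02 12:00", "2021-04-04 12:00"),  # 30 d after discharge
            _a("R2", "RB1", "2021-03-01 08:00", "2021-03-03 12:00"),
            _a("R2", "RB2", "2021-04-03 12:00", "2021-04-05 12:00"),  # 31 d after discharge
        ]),
        {"kept_courses": {"R1": 1, "R2": 2}, "readmission_excluded": 1},
    )

    f["twelve_hour_stay"] = Fixture(
        "twelve_hour_stay",
        _presc([
            _o("S1", "S1O1", "2021-03-01 19:00", "2021-03-04 10:00", setting="discharge"),
            _o("S2", "S2O1", "2021-03-01 19:00", "2021-03-04 10:00", setting="discharge"),
        ]),
        _adm([
            _a("S1", "SA1", "2021-03-01 08:00", "2021-03-01 20:00"),
            _a("S2", "SA2", "2021-03-01 08:00", "2021-03-01 19:59"),
        ]),
        {"included": {"SA1": True, "SA2": False}},
    )

    f["dual_indication"] = Fixture(
        "dual_indication",
        _presc([
            _o("D1", "D1O1", "2021-03-01 08:00", "2021-03-04 10:00", ind="UTI-cystitis"),
            _o("D1", "D1O2", "2021-03-01 08:00", "2021-03-04 10:00", ind="RTI-CAP_mild_moderate",
               atc="J01DD04", drug="ceftriaxone"),
        ]),
        _adm([_a("D1", "DA1", "2021-03-01 07:00", "2021-03-05 12:00")]),
        {"analysis_courses": 0, "dual_excluded": 1},
    )

    f["cancelled_order"] = Fixture(
        "cancelled_order",
        _presc([
            _o("C1", "C1O1", "2021-03-01 09:00", "2021-03-04 10:00"),
            _o("C1", "C1O2", "2021-03-01 10:00", "2021-03-03 10:00", status="cancelled"),
        ]),
        _adm([_a("C1", "CA1", "2021-03-01 08:00", "2021-03-04 12:00")]),
        {"cancelled_dropped": 1, "analysis_courses": 1},
    )

    f["pre_admission_start"] = Fixture(
        "pre_admission_start",
        _presc([
            _o("E1", "E1O1", "2021-02-27 09:00", "2021-02-28 09:00"),
            _o("E1", "E1O2", "2021-03-01 09:00", "2021-03-04 10:00"),
            _o("E2", "E2O1", "2021-03-01 08:00", "2021-03-04 10:00"),  # start == admit: kept
        ]),
        _adm([
            _a("E1", "EA1", "2021-03-01 08:00", "2021-03-04 12:00"),
            _a("E2", "EA2", "2021-03-01 08:00", "2021-03-04 12:00"),
        ]),
        {"erroneous_dropped": 1, "analysis_courses": 2},
    )

    f["cystitis_vs_complicated"] = Fixture(
        "cystitis_vs_complicated",
        _presc([_o("V1", "V1O1", "2021-03-01 08:00", "2021-03-09 10:00", ind="UTI-cystitis")]),
        _adm([_a("V1", "VA1", "2021-03-01 07:00", "2021-03-05 12:00")]),
        {"lot": {"V1": 9}, "chart_indication": "UTI-complicated", "affects_adherence": True},
    )

    f["empty"] = Fixture("empty", _presc([]), _adm([]), {"analysis_courses": 0})
    return f


FIXTURE_NAMES = tuple(_fixtures().keys())


def make_fixture(name: str) -> Fixture:
    """Return one of the tiny hand-constructed boundary datasets."""
    registry = _fixtures()
    if name not in registry:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(registry)}")
    return registry[name]
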