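"""Selection-flow reporting and dataset validation against chart review.

The flow report is the audit trail of the selection funnel: per stage,
how many records came in, how many were kept, and a histogram of removal
reasons.  Counts must telescope within each unit chain (prescription
orders -> admissions -> courses; the unit changes where orders are
assembled into courses, so telescoping is checked per unit).

Validation re-enacts the manual accuracy check: a stratified random
sample of analysed courses (200 per site by default) is compared with an
annotation file produced by human chart review, yielding the rate of
LOT disagreement, the rate of mis-registered indications, and the share
of indication errors that affect adherence assessment — those where the
guideline-recommended duration of the registered and the actual
indication differ.  Patients transferred to another hospital have an
unknown true duration; they are annotated ``unknown_transfer``, counted
separately, and excluded from the LOT-error denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ingest import ConsistencyError
from .registry import GuidelineTable, IndicationRegistry

__all__ = [
    "FlowStage",
    "flow_report",
    "sample_validation",
    "compute_accuracy",
    "AccuracyReport",
    "UNKNOWN_TRANSFER",
]

UNKNOWN_TRANSFER = "unknown_transfer"


@dataclass
class FlowStage:
    stage: str
    unit: str
    input_n: int
    kept_n: int
    reasons: dict[str, int] = field(default_factory=dict)


def flow_report(stages: list[FlowStage]) -> dict:
    """Assemble and validate the selection-flow report.

    Raises :class:`ConsistencyError` when a stage's removals do not
    account for its input/kept difference, or when consecutive stages of
    the same unit do not telescope.
    """
    for s in stages:
        removed = sum(s.reasons.values())
        if s.input_n - s.kept_n != removed:
            raise ConsistencyError(
                f"flow stage {s.stage}: input {s.input_n} - kept {s.kept_n} "
                f"!= removals {removed}"
            )
    for prev, cur in zip(stages, stages[1:]):
        if prev.unit == cur.unit and prev.kept_n != cur.input_n:
            raise ConsistencyError(
                f"flow stages do not telescope: {prev.stage} kept {prev.kept_n} "
                f"but {cur.stage} input {cur.input_n}"
            )
    return {
        "stages": [
            {"stage": s.stage, "unit": s.unit, "input_n": s.input_n,
             "kept_n": s.kept_n, "reasons": dict(s.reasons)}
            for s in stages
        ]
    }


def sample_validation(
    courses: pd.DataFrame, n_per_site: int = 200, seed: int = 0
) -> pd.DataFrame:
    """Uniform random sample of courses without replacement, per site.

    Reproducible under a fixed seed.  A site with fewer than
    ``n_per_site`` courses contributes all of them, with a warning.
    """
    rng = np.random.default_rng(seed)
    picked = []
    for site in sorted(courses["site"].unique()):
        site_courses = courses[courses["site"] == site]
        if len(site_courses) < n_per_site:
            warnings.warn(
                f"site {site}: only {len(site_courses)} courses available "
                f"(requested {n_per_site}); returning all",
                stacklevel=2,
            )
            picked.append(site_courses)
        elif n_per_site > 0:
            idx = rng.choice(len(site_courses), size=n_per_site, replace=False)
            picked.append(site_courses.iloc[np.sort(idx)])
    if not picked:
        return courses.iloc[0:0].copy()
    return pd.concat(picked).reset_index(drop=True)


@dataclass
class AccuracyReport:
    """Agreement between the extracted dataset and chart review."""

    n_screened: dict[str, int]
    transfer_count: int
    lot_error_rate: float
    indication_error_rate: float
    indication_errors_affecting_adherence: float  # fraction of all screened
    share_of_errors_affecting_adherence: float    # fraction of indication errors
    per_site: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return {
            "n_screened": dict(self.n_screened),
            "transfer_count": self.transfer_count,
            "lot_error_rate": self.lot_error_rate,
            "indication_error_rate": self.indication_error_rate,
            "indication_errors_affecting_adherence": self.indication_errors_affecting_adherence,
            "share_of_errors_affecting_adherence": self.share_of_errors_affecting_adherence,
            "per_site": {k: dict(v) for k, v in self.per_site.items()},
        }

    def format_table(self) -> str:
        lines = ["Accuracy of extracted duration and selected indications", ""]
        for site, stats in self.per_site.items():
            lines.append(
                f"{site}:  LOT errors {stats['lot_errors']:.0f}/{stats['n_lot']:.0f}"
                f" = {100 * stats['lot_error_rate']:.1f}%"
                f" | indication errors {stats['indication_errors']:.0f}/{stats['n']:.0f}"
                f" = {100 * stats['indication_error_rate']:.1f}%"
                f" | transfers {stats['transfers']:.0f}"
            )
        n = self.n_screened["total"]
        lines.append(
            f"Total: LOT error rate {100 * self.lot_error_rate:.1f}%"
            f" | indication error rate {100 * self.indication_error_rate:.1f}%"
            f" | errors affecting adherence {100 * self.indication_errors_affecting_adherence:.1f}%"
            f" of {n} screened"
        )
        return "\n".join(lines)


def _ranges_differ(g: GuidelineTable, registry, a: str, b: str) -> bool:
    ea = g.get(a) if g.assessable(a, registry) else None
    eb = g.get(b) if g.assessable(b, registry) else None
    if ea is None and eb is None:
        return False
    if (ea is None) != (eb is None):
        return True
    return (ea.min_days, ea.max_days) != (eb.min_days, eb.max_days)


def compute_accuracy(
    sample: pd.DataFrame,
    annotations: pd.DataFrame,
    guidelines: GuidelineTable | None = None,
    registry: IndicationRegistry | None = None,
) -> AccuracyReport:
    """Compare sampled courses with their chart-review annotations.

    ``sample`` carries the extracted values (``course_id``, ``site``,
    ``lot_days``, ``indication_code``); ``annotations`` the chart truth
    (``course_id``, ``chart_lot_days`` — integer or ``unknown_transfer``
    — and ``chart_indication``).  Every sampled course must be
    annotated.  An indication error affects adherence when the
    guideline duration ranges of the registered and the chart indication
    differ.
    """
    guidelines = guidelines or GuidelineTable.default()
    registry = registry or IndicationRegistry.default()
    ann = annotations.set_index("course_id")
    missing = [c for c in sample["course_id"] if c not in ann.index]
    if missing:
        raise ConsistencyError(f"unannotated sampled course(s): {missing[:5]}")

    merged = sample.merge(annotations, on="course_id", validate="one_to_one")
    chart_lot = merged["chart_lot_days"]
    transfer = chart_lot.astype(str) == UNKNOWN_TRANSFER
    lot_ok_denom = ~transfer
    lot_error = pd.Series(False, index=merged.index)
    lot_error[lot_ok_denom] = (
        merged.loc[lot_ok_denom, "lot_days"].astype(int)
        != chart_lot[lot_ok_denom].astype(float).astype(int)
    ).to_numpy(dtype=bool)
    ind_error = merged["indication_code"] != merged["chart_indication"]
    affects = ind_error & merged.apply(
        lambda r: _ranges_differ(guidelines, registry, r["indication_code"], r["chart_indication"]),
        axis=1,
    )

    per_site = {}
    n_screened = {}
    for site in sorted(merged["site"].unique()):
        m = merged["site"] == site
        n = int(m.sum())
        n_lot = int((m & lot_ok_denom).sum())
        n_screened[site] = n
        per_site[site] = {
            "n": n,
            "n_lot": n_lot,
            "transfers": int((m & transfer).sum()),
            "lot_errors": int((m & lot_error).sum()),
            "lot_error_rate": float((m & lot_error).sum() / n_lot) if n_lot else float("nan"),
            "indication_errors": int((m & ind_error).sum()),
            "indication_error_rate": float((m & ind_error).sum() / n) if n else float("nan"),
        }
    n_total = len(merged)
    n_lot_total = int(lot_ok_denom.sum())
    n_ind_err = int(ind_error.sum())
    n_screened["total"] = n_total
    return AccuracyReport(
        n_screened=n_screened,
        transfer_count=int(transfer.sum()),
        lot_error_rate=float(lot_error.sum() / n_lot_total) if n_lot_total else float("nan"),
        indication_error_rate=float(n_ind_err / n_total) if n_total else float("nan"),
        indication_errors_affecting_adherence=float(affects.sum() / n_total) if n_total else float("nan"),
        share_of_errors_affecting_adherence=float(affects.sum() / n_ind_err) if n_ind_err else float("nan"),
        per_site=per_site,
    )
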