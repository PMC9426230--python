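"""End-to-end orchestration: raw tables -> per-indication summary.

Stage order mirrors the surveillance funnel: parse and clean the two
extracts, select the cohort, assemble treatment courses, compute the
course metrics and aggregate per indication.  All stage logs are
collected into one exclusion table and a selection-flow report.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cohort as cohort_mod
from . import course_builder, ingest, metrics
from .registry import GuidelineTable, IndicationRegistry
from .report_validate import FlowStage, flow_report

__all__ = ["PipelineConfig", "PipelineResult", "run_tables", "run_files"]


@dataclass
class PipelineConfig:
    atc_prefixes: tuple[str, ...] = ("J01",)
    gap_hours: float = 24.0
    outpatient_gap_hours: float = 24.0
    readmission_window_days: float = 30.0
    max_course_days: int = 21
    adherence_margin_days: int = 1
    min_courses: int = 20
    extraction_time: pd.Timestamp | None = None
    registry: IndicationRegistry = field(default_factory=IndicationRegistry.default)
    guidelines: GuidelineTable = field(default_factory=GuidelineTable.default)


@dataclass
class PipelineResult:
    orders: pd.DataFrame            # cleaned orders with admission attribution
    admissions: pd.DataFrame
    decisions: pd.DataFrame         # one CohortDecision per admission
    all_courses: pd.DataFrame
    analysis_courses: pd.DataFrame
    course_metrics: pd.DataFrame
    summary: pd.DataFrame
    flow: dict
    exclusion_log: pd.DataFrame
    warnings_log: pd.DataFrame

    def write_outputs(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.orders.to_csv(out / "orders_clean.csv", index=False)
        self.decisions.to_csv(out / "cohort_decisions.csv", index=False)
        self.all_courses.to_csv(out / "courses.csv", index=False)
        self.course_metrics.to_csv(out / "course_metrics.csv", index=False)
        summary = self.summary.copy()
        summary.to_csv(out / "summary_by_indication.csv", index=False)
        self.exclusion_log.to_csv(out / "exclusion_log.csv", index=False)
        import json

        with open(out / "flow_report.json", "w") as fh:
            json.dump(self.flow, fh, indent=2)
        with open(out / "summary_by_indication.json", "w") as fh:
            json.dump({
                "rows": summary.to_dict(orient="records"),
                "excluded_pool_n": self.summary.attrs.get("excluded_pool_n", 0),
                "excluded_codes": self.summary.attrs.get("excluded_codes", []),
                "quantile_method": self.summary.attrs.get("quantile_method", "linear"),
            }, fh, indent=2, default=str)


def _hist(log: pd.DataFrame) -> dict[str, int]:
    return dict(Counter(log["reason_code"])) if len(log) else {}


def run_tables(
    prescriptions_raw: pd.DataFrame,
    admissions_raw: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full pipeline on raw (string-typed or parsed) tables."""
    cfg = config or PipelineConfig()

    orders0, presc_rejects, warnings_log = ingest.parse_prescriptions(
        prescriptions_raw, registry=cfg.registry, extraction_time=cfg.extraction_time
    )
    admissions, adm_rejects = ingest.parse_admissions(admissions_raw)
    orders1, log_atc = ingest.filter_atc(orders0, cfg.atc_prefixes)
    orders2, log_cancelled = ingest.drop_cancelled(orders1)
    orders3, log_erroneous = ingest.drop_erroneous(orders2, admissions)

    decisions = cohort_mod.build_cohort(admissions, orders3)
    n_included = int(decisions["included"].sum())
    cohort_hist = dict(Counter(
        cohort_mod.primary_reason(r) for r in decisions.loc[~decisions["included"], "reason_codes"]
    ))

    all_courses, analysis, episode_log, course_excl_log = course_builder.build_courses(
        orders3, admissions, decisions,
        registry=cfg.registry,
        gap_hours=cfg.gap_hours,
        outpatient_gap_hours=cfg.outpatient_gap_hours,
        readmission_window_days=cfg.readmission_window_days,
        max_days=cfg.max_course_days,
    )

    cm = metrics.course_metrics(
        analysis, orders3, admissions,
        guidelines=cfg.guidelines, registry=cfg.registry,
        margin_days=cfg.adherence_margin_days,
    )
    summary = metrics.summarize_by_indication(
        cm, guidelines=cfg.guidelines, registry=cfg.registry, min_courses=cfg.min_courses
    )

    stages = [
        FlowStage("parse_prescriptions", "orders", len(prescriptions_raw), len(orders0), _hist(presc_rejects)),
        FlowStage("atc_filter", "orders", len(orders0), len(orders1), _hist(log_atc)),
        FlowStage("drop_cancelled", "orders", len(orders1), len(orders2), _hist(log_cancelled)),
        FlowStage("drop_erroneous", "orders", len(orders2), len(orders3), _hist(log_erroneous)),
        FlowStage("parse_admissions", "admissions", len(admissions_raw), len(admissions), _hist(adm_rejects)),
        FlowStage("cohort_selection", "admissions", len(admissions), n_included, cohort_hist),
        FlowStage("episode_selection", "courses", len(all_courses),
                  len(all_courses) - len(episode_log), _hist(episode_log)),
        FlowStage("course_exclusions", "courses", len(all_courses) - len(episode_log),
                  len(analysis), _hist(course_excl_log)),
    ]
    flow = flow_report(stages)

    exclusion_log = pd.concat(
        [presc_rejects, adm_rejects, log_atc, log_cancelled, log_erroneous,
         episode_log, course_excl_log],
        ignore_index=True,
    )
    return PipelineResult(
        orders=orders3, admissions=admissions, decisions=decisions,
        all_courses=all_courses, analysis_courses=analysis,
        course_metrics=cm, summary=summary, flow=flow,
        exclusion_log=exclusion_log, warnings_log=warnings_log,
    )


def run_files(
    prescriptions_path: str | Path,
    admissions_path: str | Path,
    config: PipelineConfig | None = None,
    delimiter: str = ",",
) -> PipelineResult:
    presc = pd.read_csv(prescriptions_path, sep=delimiter, dtype=str)
    adm = pd.read_csv(admissions_path, sep=delimiter, dtype=str)
    return run_tables(presc, adm, config)
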