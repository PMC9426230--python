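"""Course assembly: merging, outpatient linkage, episode selection,
definitive indication, course-level exclusions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from abxlot import course_builder, ingest, pipeline
from abxlot.synthetic_emr import make_fixture
from conftest import make_order, orders_frame, random_intervals
from oracles import merge_oracle

T = pd.Timestamp


def _orders(rows, registry, adm="A1"):
    orders, rejects, _ = ingest.parse_prescriptions(orders_frame(rows), registry)
    assert rejects.empty
    return orders.assign(admission_id=adm)


class TestMergeConsecutive:
    def test_gap_within_tolerance_merges(self, registry):
        orders = _orders([
            make_order(oid="A", start="2021-03-01 08:00", stop="2021-03-03 08:00"),
            make_order(oid="B", start="2021-03-03 14:00", stop="2021-03-05 08:00"),  # 6 h gap
        ], registry)
        episodes = course_builder.merge_consecutive(orders)
        assert len(episodes) == 1
        assert set(episodes[0]["order_id"]) == {"A", "B"}

    def test_gap_beyond_tolerance_splits(self, registry):
        orders = _orders([
            make_order(oid="A", start="2021-03-01 08:00", stop="2021-03-03 08:00"),
            make_order(oid="B", start="2021-03-05 08:00", stop="2021-03-06 08:00"),  # 48 h gap
        ], registry)
        episodes = course_builder.merge_consecutive(orders)
        assert [set(e["order_id"]) for e in episodes] == [{"A"}, {"B"}]

    def test_identical_intervals_are_one_episode(self, registry):
        orders = _orders([
            make_order(oid="A"), make_order(oid="B"),
        ], registry)
        assert len(course_builder.merge_consecutive(orders)) == 1

    @pytest.mark.parametrize("gap_hours", [6.0, 24.0, 48.0])
    def test_matches_pairwise_closure_oracle(self, registry, gap_hours):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(1, 9))
            intervals = random_intervals(rng, n)
            rows = [make_order(oid=f"O{i}", start=str(s), stop=str(e))
                    for i, (s, e) in enumerate(intervals)]
            orders = _orders(rows, registry)
            got = {frozenset(e["order_id"]) for e in course_builder.merge_consecutive(orders, gap_hours)}
            want = set(merge_oracle(
                [(f"O{i}", s, e) for i, (s, e) in enumerate(intervals)], gap_hours))
            assert got == want


class TestLinkOutpatient:
    def _episode(self, registry):
        return _orders([make_order(start="2021-03-01 08:00", stop="2021-03-02 20:00")], registry)

    def _outpatient(self, registry, start, stop, oid="OP1"):
        orders, _, _ = ingest.parse_prescriptions(orders_frame([
            make_order(oid=oid, setting="outpatient", ind=None, start=start, stop=stop),
        ]), registry)
        return orders.assign(admission_id=None)

    def test_within_24h_linked(self, registry):
        # inpatient stop Tue 20:00, outpatient start Wed 10:00
        out = self._outpatient(registry, "2021-03-03 10:00", "2021-03-06 08:00")
        extended, linked = course_builder.link_outpatient(self._episode(registry), out)
        assert linked == ["OP1"]
        assert extended["stop"].max() == T("2021-03-06 08:00")

    def test_beyond_24h_not_linked(self, registry):
        out = self._outpatient(registry, "2021-03-04 02:00", "2021-03-06 08:00")  # 30 h later
        extended, linked = course_builder.link_outpatient(self._episode(registry), out)
        assert linked == []
        assert extended["stop"].max() == T("2021-03-02 20:00")

    def test_chained_linkage_extends_frontier(self, registry):
        orders, _, _ = ingest.parse_prescriptions(orders_frame([
            make_order(oid="OP1", setting="outpatient", ind=None,
                       start="2021-03-03 10:00", stop="2021-03-05 08:00"),
            make_order(oid="OP2", setting="outpatient", ind=None,
                       start="2021-03-06 02:00", stop="2021-03-08 08:00"),  # within 24 h of OP1's stop
        ]), registry)
        extended, linked = course_builder.link_outpatient(
            self._episode(registry), orders.assign(admission_id=None))
        assert linked == ["OP1", "OP2"]

    def test_no_outpatient_orders_is_identity(self, registry):
        episode = self._episode(registry)
        extended, linked = course_builder.link_outpatient(episode, episode.iloc[0:0])
        assert linked == [] and extended.equals(episode)

    def test_course_stop_never_decreases(self, registry):
        episode = self._episode(registry)
        out = self._outpatient(registry, "2021-03-02 10:00", "2021-03-02 12:00")  # inside episode
        extended, _ = course_builder.link_outpatient(episode, out)
        assert extended["stop"].max() >= episode["stop"].max()


class TestDefinitiveIndication:
    def test_last_registered_wins(self, registry):
        episode = _orders([
            make_order(oid="O1", ind="sepsis_unknown", start="2021-03-01 08:00", stop="2021-03-03 08:00"),
            make_order(oid="O2", ind="RTI-CAP_mild_moderate", start="2021-03-03 08:00", stop="2021-03-05 08:00"),
        ], registry)
        ind, dual, combo = course_builder.resolve_definitive_indication(episode)
        assert ind == "RTI-CAP_mild_moderate" and not dual

    def test_simultaneous_same_indication_is_combination(self, registry):
        episode = _orders([
            make_order(oid="O1", ind="sepsis_unknown", atc="J01CA04"),
            make_order(oid="O2", ind="sepsis_unknown", atc="J01GB03", drug="gentamicin"),
        ], registry)
        ind, dual, combo = course_builder.resolve_definitive_indication(episode)
        assert ind == "sepsis_unknown" and not dual and combo

    def test_simultaneous_different_indications_flag_dual(self, registry):
        episode = _orders([
            make_order(oid="O1", ind="UTI-cystitis"),
            make_order(oid="O2", ind="RTI-CAP_mild_moderate"),
        ], registry)
        ind, dual, _ = course_builder.resolve_definitive_indication(episode)
        assert ind is None and dual

    def test_outpatient_orders_carry_no_registration(self, registry):
        rows = [
            make_order(oid="O1", ind="UTI-cystitis", start="2021-03-01 08:00", stop="2021-03-03 08:00"),
            make_order(oid="O2", setting="outpatient", ind=None,
                       start="2021-03-03 10:00", stop="2021-03-06 08:00"),
        ]
        orders, _, _ = ingest.parse_prescriptions(orders_frame(rows), registry)
        ind, dual, _ = course_builder.resolve_definitive_indication(orders)
        assert ind == "UTI-cystitis"


class TestCourseExclusions:
    def _course(self, lot, ind, flags=""):
        return pd.DataFrame([{
            "course_id": "C1", "patient_id": "P1", "admission_id": "A1", "site": "site_0",
            "episode_index": 1, "member_order_ids": "O1",
            "course_start": T("2021-03-01 08:00"), "course_stop": T("2021-03-05 08:00"),
            "definitive_indication": ind, "is_combination": False,
            "lot_days": lot, "exclusion_flags": flags,
        }])

    @pytest.mark.parametrize(
        "lot,ind,reason",
        [
            (25, "UTI-cystitis", "over_21_days"),
            (14, "s_aureus_bacteraemia", "long_treatment_indication"),
            (4, "prophylaxis", "prophylaxis"),
        ],
    )
    def test_excluded_with_reason(self, registry, lot, ind, reason):
        kept, log = course_builder.apply_course_exclusions(self._course(lot, ind), registry)
        assert kept.empty
        assert log.iloc[0]["reason_code"] == reason

    def test_ordinary_course_kept(self, registry):
        kept, log = course_builder.apply_course_exclusions(self._course(7, "UTI-cystitis"), registry)
        assert len(kept) == 1 and log.empty


class TestEpisodeSelection:
    def test_second_episode_within_admission_excluded(self, registry):
        fx = make_fixture("gap_boundary")
        result = pipeline.run_tables(fx.prescriptions, fx.admissions)
        # patient G2's split course keeps only the initial episode
        assert (result.exclusion_log["reason_code"] == "non_initial_episode").sum() == 1
        g2 = result.analysis_courses[result.analysis_courses["patient_id"] == "G2"]
        assert len(g2) == 1 and g2.iloc[0]["episode_index"] == 1

    def test_readmission_window_day30_vs_day31(self):
        fx = make_fixture("readmission_boundary")
        result = pipeline.run_tables(fx.prescriptions, fx.admissions)
        counts = result.analysis_courses.groupby("patient_id").size()
        assert counts["R1"] == fx.expected["kept_courses"]["R1"]
        assert counts["R2"] == fx.expected["kept_courses"]["R2"]
        assert (result.exclusion_log["reason_code"] == "readmission_episode").sum() == 1


class TestDeterminism:
    def test_identical_inputs_identical_course_tables(self, registry):
        from abxlot.synthetic_emr import SimConfig, simulate

        res = simulate(SimConfig(n_patients=60, seed=5))
        cfg = pipeline.PipelineConfig(extraction_time=res.extraction_time)
        a = pipeline.run_tables(res.prescriptions, res.admissions, cfg)
        b = pipeline.run_tables(res.prescriptions, res.admissions, cfg)
        assert a.all_courses.to_csv(index=False) == b.all_courses.to_csv(index=False)

    def test_every_order_lands_in_at_most_one_course(self):
        from abxlot.synthetic_emr import SimConfig, simulate

        res = simulate(SimConfig.noiseless(n_patients=120, seed=9))
        result = pipeline.run_tables(
            res.prescriptions, res.admissions,
            pipeline.PipelineConfig(extraction_time=res.extraction_time))
        member_ids = [oid for m in result.all_courses["member_order_ids"] for oid in m.split("|")]
        assert len(member_ids) == len(set(member_ids))
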