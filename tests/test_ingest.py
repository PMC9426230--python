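"""Parsing, validation and the three cleaning filters."""

from __future__ import annotations

import pandas as pd
import pytest

from abxlot import ingest
from abxlot.ingest import ConsistencyError, SchemaError
from abxlot.synthetic_emr import SimConfig, simulate
from conftest import admissions_frame, make_admission, make_order, orders_frame


class TestParsePrescriptions:
    def test_well_formed_rows_parse_identically(self, registry):
        raw = orders_frame([make_order(oid=f"O{i}") for i in range(3)])
        orders, rejects, warnings = ingest.parse_prescriptions(raw, registry)
        assert len(orders) == 3 and rejects.empty and warnings.empty
        assert orders["start"].dtype.kind == "M"

    @pytest.mark.parametrize(
        "row,reason",
        [
            (make_order(stop="2021-02-28 08:00"), "negative_duration"),
            (make_order(ind="not_a_code"), "unknown_indication"),
            (make_order(ind=None), "missing_indication"),
            (make_order(start="yesterday-ish"), "unparseable_timestamp"),
            (make_order(setting="ambulatory"), "invalid_setting"),
        ],
    )
    def test_invalid_rows_are_rejected_with_reason(self, registry, row, reason):
        raw = orders_frame([make_order(oid="OK"), {**row, "order_id": "BAD"}])
        orders, rejects, _ = ingest.parse_prescriptions(raw, registry)
        assert list(orders["order_id"]) == ["OK"]
        assert rejects.iloc[0]["record_id"] == "BAD"
        assert rejects.iloc[0]["reason_code"] == reason

    def test_outpatient_order_may_lack_indication(self, registry):
        raw = orders_frame([make_order(setting="outpatient", ind=None)])
        orders, rejects, _ = ingest.parse_prescriptions(raw, registry)
        assert len(orders) == 1 and rejects.empty

    def test_missing_column_is_fatal(self, registry):
        raw = orders_frame([make_order()]).drop(columns=["atc_code"])
        with pytest.raises(SchemaError, match="atc_code"):
            ingest.parse_prescriptions(raw, registry)

    def test_duplicate_order_id_is_fatal(self, registry):
        raw = orders_frame([make_order(oid="X"), make_order(oid="X")])
        with pytest.raises(SchemaError, match="duplicate"):
            ingest.parse_prescriptions(raw, registry)

    def test_open_ended_stop_truncated_at_extraction_and_logged(self, registry):
        raw = orders_frame([make_order(stop=None)])
        extraction = pd.Timestamp("2021-06-01")
        orders, rejects, warnings = ingest.parse_prescriptions(raw, registry, extraction_time=extraction)
        assert rejects.empty
        assert orders.loc[0, "stop"] == extraction
        assert bool(orders.loc[0, "open_ended"])
        assert warnings.iloc[0]["reason_code"] == "open_ended"


class TestParseAdmissions:
    def test_disjoint_stays_accepted(self):
        raw = admissions_frame([
            make_admission(aid="A1", admit="2021-03-01 08:00", discharge="2021-03-02 08:00"),
            make_admission(aid="A2", admit="2021-03-05 08:00", discharge="2021-03-06 08:00"),
        ])
        adm, rejects = ingest.parse_admissions(raw)
        assert len(adm) == 2 and rejects.empty

    def test_overlapping_stays_same_patient_fatal(self):
        raw = admissions_frame([
            make_admission(aid="A1", admit="2021-03-01 08:00", discharge="2021-03-04 08:00"),
            make_admission(aid="A2", admit="2021-03-03 08:00", discharge="2021-03-06 08:00"),
        ])
        with pytest.raises(ConsistencyError, match="overlapping"):
            ingest.parse_admissions(raw)

    def test_nonpositive_stay_row_rejected(self):
        raw = admissions_frame([
            make_admission(aid="A1", admit="2021-03-01 08:00", discharge="2021-03-01 08:00"),
        ])
        adm, rejects = ingest.parse_admissions(raw)
        assert adm.empty and rejects.iloc[0]["reason_code"] == "nonpositive_stay"

    def test_short_stay_survives_cleaning_cohort_filters_later(self):
        # a 10-h stay is valid input; the 12-h rule is a cohort criterion
        raw = admissions_frame([
            make_admission(admit="2021-03-01 08:00", discharge="2021-03-01 18:00"),
        ])
        adm, rejects = ingest.parse_admissions(raw)
        assert len(adm) == 1 and rejects.empty


class TestFilters:
    def test_atc_prefix_match(self, registry):
        raw = orders_frame([
            make_order(oid="O1", atc="J01CA04"),
            make_order(oid="O2", atc="P01AB01", drug="metronidazole"),
        ])
        orders, _, _ = ingest.parse_prescriptions(raw, registry)
        kept, log = ingest.filter_atc(orders)
        assert list(kept["order_id"]) == ["O1"]
        assert log.iloc[0]["record_id"] == "O2"
        kept2, log2 = ingest.filter_atc(orders, ("J01", "P01AB"))
        assert len(kept2) == 2 and log2.empty

    def test_empty_prefix_list_rejected(self, registry):
        orders, _, _ = ingest.parse_prescriptions(orders_frame([make_order()]), registry)
        with pytest.raises(ValueError):
            ingest.filter_atc(orders, ())

    def test_drop_cancelled(self, registry):
        raw = orders_frame([
            make_order(oid="O1", status="completed"),
            make_order(oid="O2", status="cancelled"),
        ])
        orders, _, _ = ingest.parse_prescriptions(raw, registry)
        kept, log = ingest.drop_cancelled(orders)
        assert list(kept["order_id"]) == ["O1"]
        assert log.iloc[0]["reason_code"] == "cancelled"

    def test_drop_cancelled_empty_table(self, registry):
        orders, _, _ = ingest.parse_prescriptions(orders_frame([]), registry)
        kept, log = ingest.drop_cancelled(orders)
        assert kept.empty and log.empty


class TestDropErroneous:
    @pytest.fixture
    def admissions(self):
        adm, _ = ingest.parse_admissions(admissions_frame([
            make_admission(admit="2021-06-02 08:00", discharge="2021-06-08 12:00"),
        ]))
        return adm

    def _clean(self, registry, rows):
        orders, _, _ = ingest.parse_prescriptions(orders_frame(rows), registry)
        return orders

    def test_start_date_before_admission_date_dropped(self, registry, admissions):
        orders = self._clean(registry, [make_order(start="2021-06-01 22:00", stop="2021-06-03 10:00")])
        kept, log = ingest.drop_erroneous(orders, admissions)
        assert kept.empty
        assert log.iloc[0]["reason_code"] == "erroneous_pre_admission"

    def test_start_at_admit_instant_kept(self, registry, admissions):
        orders = self._clean(registry, [make_order(start="2021-06-02 08:00", stop="2021-06-03 10:00")])
        kept, log = ingest.drop_erroneous(orders, admissions)
        assert len(kept) == 1 and log.empty
        assert kept.loc[0, "admission_id"] == "A1"

    def test_same_date_before_admit_time_kept(self, registry, admissions):
        # erroneous only when the calendar DATE precedes the admission date
        orders = self._clean(registry, [make_order(start="2021-06-02 06:00", stop="2021-06-03 10:00")])
        kept, log = ingest.drop_erroneous(orders, admissions)
        assert len(kept) == 1 and log.empty

    def test_outpatient_order_untouched(self, registry, admissions):
        orders = self._clean(registry, [
            make_order(setting="outpatient", ind=None, start="2021-07-01 08:00", stop="2021-07-03 08:00"),
        ])
        kept, log = ingest.drop_erroneous(orders, admissions)
        assert len(kept) == 1 and log.empty
        assert pd.isna(kept.loc[0, "admission_id"])

    def test_inpatient_order_without_admission_is_orphan(self, registry, admissions):
        orders = self._clean(registry, [make_order(pid="P_other")])
        kept, log = ingest.drop_erroneous(orders, admissions)
        assert kept.empty and log.iloc[0]["reason_code"] == "orphan_order"

    def test_discharge_order_within_24h_grace_joined(self, registry, admissions):
        orders = self._clean(registry, [
            make_order(setting="discharge", start="2021-06-09 10:00", stop="2021-06-12 10:00"),
        ])
        kept, log = ingest.drop_erroneous(orders, admissions)
        assert len(kept) == 1 and kept.loc[0, "admission_id"] == "A1"


@pytest.fixture(scope="module")
def sim_tables(registry):
    res = simulate(SimConfig(n_patients=150, seed=11))
    orders, rejects, _ = ingest.parse_prescriptions(
        res.prescriptions, registry, extraction_time=res.extraction_time
    )
    adm, _ = ingest.parse_admissions(res.admissions)
    return orders, adm


class TestFilterAlgebra:
    """Conservation, idempotence and commutativity of the cleaning filters."""

    def test_conservation_per_stage(self, sim_tables):
        orders, adm = sim_tables
        o1, l1 = ingest.filter_atc(orders)
        o2, l2 = ingest.drop_cancelled(o1)
        o3, l3 = ingest.drop_erroneous(o2, adm)
        assert len(orders) == len(o1) + len(l1)
        assert len(o1) == len(o2) + len(l2)
        assert len(o2) == len(o3) + len(l3)
        assert len(orders) == len(o3) + len(l1) + len(l2) + len(l3)

    def test_idempotence(self, sim_tables):
        orders, adm = sim_tables
        once, _ = ingest.drop_cancelled(orders)
        twice, log2 = ingest.drop_cancelled(once)
        assert log2.empty and twice.equals(once)
        e_once, _ = ingest.drop_erroneous(orders, adm)
        e_twice, e_log2 = ingest.drop_erroneous(e_once, adm)
        assert e_log2.empty
        assert list(e_twice["order_id"]) == list(e_once["order_id"])

    def test_filters_commute(self, sim_tables):
        orders, adm = sim_tables
        a1, _ = ingest.drop_cancelled(orders)
        a2, _ = ingest.drop_erroneous(a1, adm)
        b1, _ = ingest.drop_erroneous(orders, adm)
        b2, _ = ingest.drop_cancelled(b1)
        assert set(a2["order_id"]) == set(b2["order_id"])
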