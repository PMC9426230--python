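from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from abxlot.ingest import ADMISSION_COLUMNS, PRESCRIPTION_COLUMNS
from abxlot.registry import GuidelineTable, IndicationRegistry


@pytest.fixture(scope="session")
def registry() -> IndicationRegistry:
    return IndicationRegistry.default()


@pytest.fixture(scope="session")
def guidelines() -> GuidelineTable:
    return GuidelineTable.default()


def make_order(pid="P1", oid="O1", start="2021-03-01 08:00", stop="2021-03-03 10:00",
               setting="inpatient", status="completed", ind="UTI-cystitis",
               atc="J01CA04", drug="amoxicillin", specialty="internal_medicine") -> dict:
    return {
        "patient_id": pid, "order_id": oid, "atc_code": atc, "drug_name": drug,
        "start": start, "stop": stop, "setting": setting, "status": status,
        "indication_code": ind, "prescriber_specialty": specialty,
    }


def orders_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=PRESCRIPTION_COLUMNS)


def make_admission(pid="P1", aid="A1", admit="2021-03-01 07:00", discharge="2021-03-05 12:00",
                   ward="general", age=50, site="site_0") -> dict:
    return {"patient_id": pid, "admission_id": aid, "admit": admit, "discharge": discharge,
            "ward": ward, "age_years": age, "site": site}


def admissions_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=ADMISSION_COLUMNS + ["site"])


def random_intervals(rng: np.random.Generator, n: int, span_days: int = 6):
    """Random minute-resolution half-open intervals inside a short window."""
    base = pd.Timestamp("2021-03-01")
    out = []
    for _ in range(n):
        s = int(rng.integers(0, span_days * 24 * 60))
        length = int(rng.integers(0, 3 * 24 * 60))
        start = base + pd.Timedelta(minutes=s)
        out.append((start, start + pd.Timedelta(minutes=length)))
    return out
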