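from __future__ import annotations

from datetime import date, timedelta

import pytest

from gclot import StudyConfig, default_catalog
from gclot.records import PatientRecord, PrescriptionRecord

BASE = date(2016, 1, 1)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def config():
    return StudyConfig()


def patient(pid="X", last_day=2000, death_day=None, birth=(1950, 1)):
    """A minimal patient whose follow-up horizon is ``last_day`` days after
    the stream origin (far enough that ordinary lines end by gap)."""
    return PatientRecord(
        patient_id=pid,
        sex="male",
        birth_year_month=birth,
        death_date=BASE + timedelta(days=death_day) if death_day is not None else None,
        last_record_date=BASE + timedelta(days=last_day),
        hospital_is_designated_cancer=True,
        hospital_departments=frozenset({"surgery"}),
        hospital_bed_band="200-<500",
        adl_items=("independent",) * 10,
    )


def rx_stream(stream, pid="X"):
    """[(day, agent_code), ...] -> PrescriptionRecords anchored at BASE."""
    return [
        PrescriptionRecord(pid, BASE + timedelta(days=d), a) for d, a in stream
    ]


def day_of(d: date) -> int:
    return (d - BASE).days
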