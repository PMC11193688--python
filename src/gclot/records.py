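"""Patient-level claims domain types.

A :class:`ClaimsBundle` is the universal input of the pipeline: one patient
table plus three event tables (prescriptions, diagnoses, procedures), with
referential integrity and per-patient date ordering enforced at
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

SEXES = ("male", "female", "unknown")
ADL_STATES = ("independent", "dependent", "missing")
BED_BANDS = ("<200", "200-<500", ">=500")


@dataclass
class PatientRecord:
    patient_id: str
    sex: str
    birth_year_month: tuple[int, int]  # (year, month)
    death_date: date | None
    last_record_date: date
    hospital_is_designated_cancer: bool
    hospital_departments: frozenset[str]
    hospital_bed_band: str
    adl_items: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"{self.patient_id}: bad sex {self.sex!r}")
        if self.hospital_bed_band not in BED_BANDS:
            raise ValueError(f"{self.patient_id}: bad bed band {self.hospital_bed_band!r}")
        if len(self.adl_items) != 10:
            raise ValueError(f"{self.patient_id}: adl_items must have exactly 10 entries")
        for item in self.adl_items:
            if item not in ADL_STATES:
                raise ValueError(f"{self.patient_id}: bad ADL state {item!r}")
        if self.death_date is not None and self.death_date > self.last_record_date:
            raise ValueError(f"{self.patient_id}: death_date after last_record_date")

    def birth_date_midmonth(self) -> date:
        """Imputed birth date: claims carry year/month only; the 15th is used."""
        y, m = self.birth_year_month
        return date(y, m, 15)

    def age_at(self, when: date) -> int:
        b = self.birth_date_midmonth()
        return when.year - b.year - ((when.month, when.day) < (b.month, b.day))


@dataclass(frozen=True, order=True)
class PrescriptionRecord:
    patient_id: str
    date: date
    agent_code: str


@dataclass(frozen=True, order=True)
class DiagnosisRecord:
    patient_id: str
    date: date
    code: str
    category: str = "other"  # gastric_cancer | recurrence | comorbidity:x | metastasis:x | other


@dataclass(frozen=True, order=True)
class ProcedureRecord:
    patient_id: str
    date: date
    code: str
    is_gc_resection: bool = False
    is_trial_participation: bool = False


@dataclass
class ClaimsBundle:
    patients: dict[str, PatientRecord]
    prescriptions: list[PrescriptionRecord] = field(default_factory=list)
    diagnoses: list[DiagnosisRecord] = field(default_factory=list)
    procedures: list[ProcedureRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()
        self.sort_events()

    def validate(self) -> None:
        for kind in ("prescriptions", "diagnoses", "procedures"):
            for ev in getattr(self, kind):
                if ev.patient_id not in self.patients:
                    raise ValueError(
                        f"{kind[:-1]} references unknown patient {ev.patient_id!r}"
                    )
                last = self.patients[ev.patient_id].last_record_date
                if ev.date > last:
                    raise ValueError(
                        f"{kind[:-1]} for {ev.patient_id} dated {ev.date} after "
                        f"last_record_date {last}"
                    )

    def sort_events(self) -> None:
        self.prescriptions.sort()
        self.diagnoses.sort()
        self.procedures.sort()

    # -- per-patient views -------------------------------------------------

    def prescriptions_for(self, patient_id: str) -> list[PrescriptionRecord]:
        return [p for p in self.prescriptions if p.patient_id == patient_id]

    def diagnoses_for(self, patient_id: str) -> list[DiagnosisRecord]:
        return [d for d in self.diagnoses if d.patient_id == patient_id]

    def procedures_for(self, patient_id: str) -> list[ProcedureRecord]:
        return [p for p in self.procedures if p.patient_id == patient_id]

    def grouped(self):
        """Yield (patient_id, patient, prescriptions, diagnoses, procedures)
        with events pre-grouped in one pass (cheaper than repeated filters)."""
        rx: dict[str, list[PrescriptionRecord]] = {pid: [] for pid in self.patients}
        dx: dict[str, list[DiagnosisRecord]] = {pid: [] for pid in self.patients}
        px: dict[str, list[ProcedureRecord]] = {pid: [] for pid in self.patients}
        for p in self.prescriptions:
            rx[p.patient_id].append(p)
        for d in self.diagnoses:
            dx[d.patient_id].append(d)
        for p in self.procedures:
            px[p.patient_id].append(p)
        for pid in sorted(self.patients):
            yield pid, self.patients[pid], rx[pid], dx[pid], px[pid]
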