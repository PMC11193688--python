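"""Readers and writers for the four claims tables and result outputs.

All tables are UTF-8 comma-delimited with ISO-8601 (YYYY-MM-DD) dates.

patients.csv
    patient_id, sex, birth_year_month (YYYY-MM), death_date (may be empty),
    last_record_date, hospital_is_designated_cancer (true/false),
    hospital_departments (``|``-joined), hospital_bed_band,
    adl_items (``|``-joined, exactly 10 entries)
prescriptions.csv   patient_id, agent_code, date
diagnoses.csv       patient_id, code, date
procedures.csv      patient_id, code, date
"""

from __future__ import annotations

import json
import re
from datetime import date, datetime
from pathlib import Path

import pandas as pd

from . import __version__
from .catalog import RegimenCatalog
from .config import StudyConfig
from .records import (
    ClaimsBundle,
    DiagnosisRecord,
    PatientRecord,
    PrescriptionRecord,
    ProcedureRecord,
)

_ISO_DATE = re.compile(r"^\d{4}-\d{2}-\d{2}$")
_ISO_MONTH = re.compile(r"^\d{4}-\d{2}$")

TABLE_FILES = {
    "patients": "patients.csv",
    "prescriptions": "prescriptions.csv",
    "diagnoses": "diagnoses.csv",
    "procedures": "procedures.csv",
}


class ClaimsFormatError(ValueError):
    """Raised for schema, parse, or referential-integrity failures."""


def _parse_date(value: str, table: str, row: int) -> date:
    if not isinstance(value, str) or not _ISO_DATE.match(value):
        raise ClaimsFormatError(
            f"{table}.csv row {row}: unparseable date {value!r} (expected YYYY-MM-DD)"
        )
    return date.fromisoformat(value)


def _read_table(path: Path, columns: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise ClaimsFormatError(f"missing input file {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ClaimsFormatError(f"{path.name}: missing columns {missing}")
    return df


def load_claims(
    claims_dir: str | Path, catalog: RegimenCatalog, config: StudyConfig
) -> ClaimsBundle:
    """Load and validate the four claims tables from ``claims_dir``.

    Diagnosis categories and procedure flags are resolved through the config
    code maps; unmapped codes fall back to ``other`` / all-false flags.
    Unknown agent codes, referential-integrity violations and non-ISO dates
    are hard errors.
    """
    claims_dir = Path(claims_dir)

    pat_df = _read_table(
        claims_dir / "patients.csv",
        [
            "patient_id", "sex", "birth_year_month", "death_date",
            "last_record_date", "hospital_is_designated_cancer",
            "hospital_departments", "hospital_bed_band", "adl_items",
        ],
    )
    patients: dict[str, PatientRecord] = {}
    for i, row in enumerate(pat_df.itertuples(index=False), start=2):
        if not _ISO_MONTH.match(row.birth_year_month):
            raise ClaimsFormatError(
                f"patients.csv row {i}: bad birth_year_month {row.birth_year_month!r}"
            )
        y, m = (int(x) for x in row.birth_year_month.split("-"))
        death = _parse_date(row.death_date, "patients", i) if row.death_date else None
        rec = PatientRecord(
            patient_id=row.patient_id,
            sex=row.sex,
            birth_year_month=(y, m),
            death_date=death,
            last_record_date=_parse_date(row.last_record_date, "patients", i),
            hospital_is_designated_cancer=row.hospital_is_designated_cancer.lower()
            == "true",
            hospital_departments=frozenset(
                d for d in row.hospital_departments.split("|") if d
            ),
            hospital_bed_band=row.hospital_bed_band,
            adl_items=tuple(row.adl_items.split("|")),
        )
        if rec.patient_id in patients:
            raise ClaimsFormatError(f"patients.csv row {i}: duplicate id {rec.patient_id}")
        patients[rec.patient_id] = rec

    rx_df = _read_table(claims_dir / "prescriptions.csv", ["patient_id", "agent_code", "date"])
    unknown = sorted(set(rx_df["agent_code"]) - set(catalog.agents))
    if unknown:
        raise ClaimsFormatError(f"prescriptions.csv: unknown agent codes {unknown}")
    lo, hi = config.study_window
    prescriptions = []
    for i, row in enumerate(rx_df.itertuples(index=False), start=2):
        d = _parse_date(row.date, "prescriptions", i)
        if not (lo <= d <= hi):
            raise ClaimsFormatError(
                f"prescriptions.csv row {i}: date {d} outside study window"
            )
        prescriptions.append(PrescriptionRecord(row.patient_id, d, row.agent_code))

    dx_df = _read_table(claims_dir / "diagnoses.csv", ["patient_id", "code", "date"])
    diagnoses = [
        DiagnosisRecord(
            row.patient_id,
            _parse_date(row.date, "diagnoses", i),
            row.code,
            config.diagnosis_code_map.get(row.code, "other"),
        )
        for i, row in enumerate(dx_df.itertuples(index=False), start=2)
    ]

    px_df = _read_table(claims_dir / "procedures.csv", ["patient_id", "code", "date"])
    procedures = []
    for i, row in enumerate(px_df.itertuples(index=False), start=2):
        flags = config.procedure_code_map.get(row.code, {})
        procedures.append(
            ProcedureRecord(
                row.patient_id,
                _parse_date(row.date, "procedures", i),
                row.code,
                bool(flags.get("is_gc_resection", False)),
                bool(flags.get("is_trial_participation", False)),
            )
        )

    try:
        return ClaimsBundle(patients, prescriptions, diagnoses, procedures)
    except ValueError as exc:  # referential integrity / ordering
        raise ClaimsFormatError(str(exc)) from exc


def write_claims(bundle: ClaimsBundle, out_dir: str | Path, overwrite: bool = False) -> None:
    """Write a bundle back to the four-table CSV layout (load round-trips)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in TABLE_FILES.values():
        if (out_dir / name).exists() and not overwrite:
            raise FileExistsError(f"{out_dir / name} exists (pass overwrite=True)")

    pat_rows = [
        {
            "patient_id": p.patient_id,
            "sex": p.sex,
            "birth_year_month": f"{p.birth_year_month[0]:04d}-{p.birth_year_month[1]:02d}",
            "death_date": p.death_date.isoformat() if p.death_date else "",
            "last_record_date": p.last_record_date.isoformat(),
            "hospital_is_designated_cancer": str(p.hospital_is_designated_cancer).lower(),
            "hospital_departments": "|".join(sorted(p.hospital_departments)),
            "hospital_bed_band": p.hospital_bed_band,
            "adl_items": "|".join(p.adl_items),
        }
        for p in (bundle.patients[k] for k in sorted(bundle.patients))
    ]
    pd.DataFrame(
        pat_rows,
        columns=[
            "patient_id", "sex", "birth_year_month", "death_date", "last_record_date",
            "hospital_is_designated_cancer", "hospital_departments",
            "hospital_bed_band", "adl_items",
        ],
    ).to_csv(out_dir / "patients.csv", index=False)

    pd.DataFrame(
        [
            {"patient_id": r.patient_id, "agent_code": r.agent_code, "date": r.date.isoformat()}
            for r in bundle.prescriptions
        ],
        columns=["patient_id", "agent_code", "date"],
    ).to_csv(out_dir / "prescriptions.csv", index=False)

    pd.DataFrame(
        [
            {"patient_id": r.patient_id, "code": r.code, "date": r.date.isoformat()}
            for r in bundle.diagnoses
        ],
        columns=["patient_id", "code", "date"],
    ).to_csv(out_dir / "diagnoses.csv", index=False)

    pd.DataFrame(
        [
            {"patient_id": r.patient_id, "code": r.code, "date": r.date.isoformat()}
            for r in bundle.procedures
        ],
        columns=["patient_id", "code", "date"],
    ).to_csv(out_dir / "procedures.csv", index=False)


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: StudyConfig,
    seed: int | None = None,
    overwrite: bool = False,
    extra_manifest: dict | None = None,
) -> list[Path]:
    """Write one CSV per named result table plus a JSON run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in tables.items():
        path = out_dir / f"{name}.csv"
        if path.exists() and not overwrite:
            raise FileExistsError(f"{path} exists (pass overwrite=True)")
        df.to_csv(path, index=False)
        written.append(path)
    manifest = {
        "software": "gclot",
        "version": __version__,
        "timestamp": datetime.now().isoformat(timespec="seconds"),
        "seed": seed,
        "config": config.to_dict(),
        "tables": {name: int(len(df)) for name, df in tables.items()},
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    mpath = out_dir / "manifest.json"
    if mpath.exists() and not overwrite:
        raise FileExistsError(f"{mpath} exists (pass overwrite=True)")
    with open(mpath, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    written.append(mpath)
    return written


def read_manifest(out_dir: str | Path) -> dict:
    with open(Path(out_dir) / "manifest.json", encoding="utf-8") as fh:
        return json.load(fh)
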