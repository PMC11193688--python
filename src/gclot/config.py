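"""Study configuration: every threshold of the analysis in one place.

The analysis is driven entirely by calendar-day thresholds (combination
window, end-of-line gap, early/late recurrence cut-off, enrollment windows,
era boundaries) plus code maps that translate opaque claim codes into
diagnosis categories and procedure flags.  Sensitivity analyses are plain
overlays of this object, never separate code paths.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date

import yaml

# days -> months conversion used for all reported durations
MONTHS_PER_DAY = 12.0 / 365.25


def _d(s: str | date) -> date:
    return s if isinstance(s, date) else date.fromisoformat(s)


#: default diagnosis code -> category map used by the synthetic generator
DEFAULT_DIAGNOSIS_CODE_MAP: dict[str, str] = {
    "GC": "gastric_cancer",
    "REC": "recurrence",
    "CM_HYPERTENSION": "comorbidity:hypertension",
    "CM_DIABETES": "comorbidity:diabetes",
    "CM_LIVER_DISEASE": "comorbidity:liver_disease",
    "CM_KIDNEY_DISEASE": "comorbidity:kidney_disease",
    "MET_PERITONEAL": "metastasis:peritoneal",
    "MET_LYMPH_NODE": "metastasis:lymph_node",
    "MET_LIVER": "metastasis:liver",
    "MET_LUNG": "metastasis:lung",
}

#: default procedure code -> flag map
DEFAULT_PROCEDURE_CODE_MAP: dict[str, dict[str, bool]] = {
    "GC_RESECTION": {"is_gc_resection": True, "is_trial_participation": False},
    "TRIAL_ENTRY": {"is_gc_resection": False, "is_trial_participation": True},
    "OTHER_PROC": {"is_gc_resection": False, "is_trial_participation": False},
}


@dataclass
class StudyConfig:
    """All tunable thresholds of the cohort and line-of-therapy rules.

    Day-difference comparisons are inclusive: "within N days" means
    ``0 <= difference <= N``.
    """

    combination_window_days: int = 90
    line_gap_days: int = 120
    early_late_threshold_days: int = 180
    surgery_after_diagnosis_days: int = 60
    adjuvant_after_surgery_days: int = 90
    min_adjuvant_prescription_days: int = 21
    min_age_years: int = 20
    adjuvant_enrollment_start: date = date(2008, 10, 1)
    recurrent_1l_window: tuple[date, date] = (date(2014, 5, 1), date(2021, 11, 24))
    era_boundaries: tuple[tuple[date, date], ...] = (
        (date(2008, 10, 1), date(2016, 5, 31)),
        (date(2016, 6, 1), date(2019, 8, 31)),
        (date(2019, 9, 1), date(2022, 3, 31)),
    )
    ramucirumab_era_split: date = date(2015, 10, 1)
    age_breaks: tuple[int, int] = (65, 75)
    lookback_days: int = 180
    study_window: tuple[date, date] = (date(2008, 4, 1), date(2022, 3, 31))
    # when False, only agents outside every catalog regimen trigger the
    # pre-surgery exclusion; when True any catalog antitumor agent does
    exclude_any_presurgery_agent: bool = True
    diagnosis_code_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_DIAGNOSIS_CODE_MAP)
    )
    procedure_code_map: dict[str, dict[str, bool]] = field(
        default_factory=lambda: dict(DEFAULT_PROCEDURE_CODE_MAP)
    )

    def __post_init__(self) -> None:
        for name in (
            "combination_window_days",
            "line_gap_days",
            "early_late_threshold_days",
            "surgery_after_diagnosis_days",
            "adjuvant_after_surgery_days",
            "min_adjuvant_prescription_days",
            "lookback_days",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.recurrent_1l_window
        if not (self.study_window[0] <= lo <= hi <= self.study_window[1]):
            raise ValueError("recurrent_1l_window must lie inside study_window")
        eras = self.era_boundaries
        for (s, e) in eras:
            if s > e:
                raise ValueError("era interval reversed")
        for (_, e_prev), (s_next, _) in zip(eras, eras[1:]):
            if s_next <= e_prev:
                raise ValueError("era intervals must be ordered and non-overlapping")

    # -- (de)serialisation ------------------------------------------------

    def replace(self, **kw) -> "StudyConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, date):
                return v.isoformat()
            if isinstance(v, tuple):
                return [conv(x) for x in v]
            return v

        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        kw = dict(d)
        for key in ("adjuvant_enrollment_start", "ramucirumab_era_split"):
            if key in kw:
                kw[key] = _d(kw[key])
        for key in ("recurrent_1l_window", "study_window"):
            if key in kw:
                kw[key] = tuple(_d(x) for x in kw[key])
        if "era_boundaries" in kw:
            kw["era_boundaries"] = tuple(
                tuple(_d(x) for x in pair) for pair in kw["era_boundaries"]
            )
        if "age_breaks" in kw:
            kw["age_breaks"] = tuple(kw["age_breaks"])
        return cls(**kw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching clinical-table convention."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def days_to_months(days: float) -> float:
    """Convert a day count to months (12/365.25 per day), 1-decimal rounded."""
    return round_half_up(days * MONTHS_PER_DAY, 1)
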