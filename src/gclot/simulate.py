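"""Synthetic longitudinal claims generator with known ground truth.

Each simulated patient is a gastric-cancer trajectory: diagnosis →
resection → adjuvant cycles (regimen mix shifting across the three
calendar eras) → optional recurrence (early/late mixture) → sequential
palliative lines with cyclic administrations → death or administrative
censoring.  A configurable share of patients carries exactly one deliberate
rule violation (pre-surgery antitumor agent, recurrence during adjuvant
therapy, ≤ 21-day adjuvant record, under-age, trial participation, late
resection, concomitant non-adjuvant agent) so every cohort rule is
exercised.

Margin construction: every generated inter-administration gap and every
recurrence-to-first-line offset stays at least ``margin_days`` away from
the active thresholds (end-of-line gap, early/late cut-off), so the ground
truth is unambiguous under the inclusive-bound convention and the pipeline
must recover it exactly.  An ``adversarial`` mode instead places gaps and
offsets exactly on the thresholds to probe the boundary convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np

from .catalog import RegimenCatalog, default_catalog
from .cohorts import assign_era
from .config import StudyConfig
from .records import (
    ClaimsBundle,
    DiagnosisRecord,
    PatientRecord,
    PrescriptionRecord,
    ProcedureRecord,
)

DAYS_PER_MONTH = 30.44

# default mixes emulate the published era shares and post-recurrent patterns
DEFAULT_ERA_REGIMEN_MIX = {
    1: {"S-1": 0.957, "SOX": 0.016, "CapeOX": 0.012, "DS": 0.015},
    2: {"S-1": 0.778, "SOX": 0.079, "CapeOX": 0.088, "DS": 0.055},
    3: {"S-1": 0.650, "SOX": 0.101, "CapeOX": 0.049, "DS": 0.200},
}

DEFAULT_EARLY_1L_MIX = {
    "PTX + RAM": 0.34, "CapeOX": 0.17, "nab-PTX + RAM": 0.10, "PTX": 0.09,
    "SP": 0.09, "XP": 0.05, "SOX": 0.05, "S-1": 0.03, "FOLFOX": 0.02,
    "nab-PTX": 0.03, "RAM": 0.02, "IRI": 0.01,
}
DEFAULT_LATE_1L_MIX = {
    "SOX": 0.263, "SP": 0.153, "CapeOX": 0.140, "S-1": 0.132,
    "PTX + RAM": 0.108, "nab-PTX + RAM": 0.049, "PTX": 0.046,
    "FOLFOX": 0.032, "XP": 0.022, "nab-PTX": 0.015, "DS": 0.010,
    "RAM": 0.008, "IRI": 0.022,
}
DEFAULT_HER2_1L_MIX = {"XP": 0.50, "CapeOX": 0.17, "PTX": 0.10, "SP": 0.12, "SOX": 0.11}
DEFAULT_2L_MIX = {
    "PTX + RAM": 0.30, "NIV": 0.25, "nab-PTX + RAM": 0.15, "IRI": 0.12,
    "FTD/TPI": 0.10, "PTX": 0.08,
}
DEFAULT_3L_MIX = {
    "NIV": 0.48, "IRI": 0.17, "PTX + RAM": 0.12, "FTD/TPI": 0.13, "nab-PTX": 0.10,
}

DEFAULT_ADJUVANT_DURATION_MONTHS = {
    "S-1": (10.5, 2.0), "SOX": (9.5, 2.5), "CapeOX": (5.7, 1.2), "DS": (11.0, 2.0),
}

DEFAULT_NEGATIVE_CASE_PROBS = {
    "no_resection_within_60d": 0.02,
    "non_adjuvant_agent_post_surgery": 0.03,
    "recurrence_before_adjuvant_end": 0.03,
    "pre_surgery_antitumor_agent": 0.03,
    "trial_participation": 0.02,
    "age": 0.02,
    "short_adjuvant": 0.02,
}

ADJUVANT_NEGATIVES = frozenset(
    {
        "no_resection_within_60d",
        "non_adjuvant_agent_post_surgery",
        "recurrence_before_adjuvant_end",
        "pre_surgery_antitumor_agent",
        "trial_participation",
        "age",
    }
)

COMORBIDITY_PREVALENCE = {
    "CM_HYPERTENSION": 0.30, "CM_DIABETES": 0.24,
    "CM_LIVER_DISEASE": 0.12, "CM_KIDNEY_DISEASE": 0.04,
}
METASTASIS_PREVALENCE = {
    "MET_PERITONEAL": 0.30, "MET_LYMPH_NODE": 0.09,
    "MET_LIVER": 0.08, "MET_LUNG": 0.07,
}


@dataclass
class SimulationParams:
    n_patients: int = 200
    seed: int = 0
    era_weights: tuple[float, float, float] = (0.357, 0.345, 0.298)
    era_regimen_mix: dict[int, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ERA_REGIMEN_MIX.items()}
    )
    cycle_interval_days: dict[str, int] = field(default_factory=lambda: {"default": 21})
    adjuvant_duration_months: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ADJUVANT_DURATION_MONTHS)
    )
    p_recurrence: float = 0.30
    early_weight: float = 0.546  # early share of the recurrence-timing mixture
    early_1l_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EARLY_1L_MIX))
    late_1l_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LATE_1L_MIX))
    her2_1l_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HER2_1L_MIX))
    mix_2l: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_2L_MIX))
    mix_3l: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_3L_MIX))
    p_her2: float = 0.09
    line_transition_probs: tuple[float, float] = (0.56, 0.36)
    p_death_after_last_line: float = 0.35
    p_event_follow_up: float = 0.5  # long follow-up after last administration
    gap_jitter_days: int = 3
    margin_days: int = 14
    negative_case_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NEGATIVE_CASE_PROBS)
    )
    adversarial: bool = False

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.margin_days < 1:
            raise ValueError("margin_days must be >= 1")
        for name, p in (
            ("p_recurrence", self.p_recurrence),
            ("early_weight", self.early_weight),
            ("p_her2", self.p_her2),
            ("p_death_after_last_line", self.p_death_after_last_line),
            ("p_event_follow_up", self.p_event_follow_up),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for label, mix in [
            ("early_1l_mix", self.early_1l_mix),
            ("late_1l_mix", self.late_1l_mix),
            ("her2_1l_mix", self.her2_1l_mix),
            ("mix_2l", self.mix_2l),
            ("mix_3l", self.mix_3l),
            *[(f"era_regimen_mix[{k}]", v) for k, v in self.era_regimen_mix.items()],
        ]:
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{label} must sum to 1 (got {total})")
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"{label} has negative weights")
        if sum(self.negative_case_probs.values()) >= 1.0:
            raise ValueError("negative_case_probs must sum to < 1")


@dataclass
class TruthLine:
    line_index: int  # 0 = adjuvant
    start: date
    last_admin: date
    regimen_label: str
    end_reason: str
    event_observed: bool

    def to_dict(self) -> dict:
        return {
            "line_index": self.line_index,
            "start": self.start.isoformat(),
            "last_admin": self.last_admin.isoformat(),
            "regimen_label": self.regimen_label,
            "end_reason": self.end_reason,
            "event_observed": self.event_observed,
        }


@dataclass
class TruthPatient:
    patient_id: str
    in_adjuvant: bool
    adjuvant_exclusion_reason: str | None
    adjuvant_regimen: str | None
    era: int | None
    in_recurrent: bool
    recurrent_exclusion_reason: str | None
    recurrence_date: date | None
    recurrence_timing: str | None
    tmab_group: str | None
    lines: list[TruthLine]

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "in_adjuvant": self.in_adjuvant,
            "adjuvant_exclusion_reason": self.adjuvant_exclusion_reason,
            "adjuvant_regimen": self.adjuvant_regimen,
            "era": self.era,
            "in_recurrent": self.in_recurrent,
            "recurrent_exclusion_reason": self.recurrent_exclusion_reason,
            "recurrence_date": self.recurrence_date.isoformat()
            if self.recurrence_date
            else None,
            "recurrence_timing": self.recurrence_timing,
            "tmab_group": self.tmab_group,
            "lines": [l.to_dict() for l in self.lines],
        }


@dataclass
class GroundTruth:
    patients: dict[str, TruthPatient]

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {pid: t.to_dict() for pid, t in sorted(self.patients.items())},
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        patients = {}
        for pid, d in raw.items():
            patients[pid] = TruthPatient(
                patient_id=d["patient_id"],
                in_adjuvant=d["in_adjuvant"],
                adjuvant_exclusion_reason=d["adjuvant_exclusion_reason"],
                adjuvant_regimen=d["adjuvant_regimen"],
                era=d["era"],
                in_recurrent=d["in_recurrent"],
                recurrent_exclusion_reason=d["recurrent_exclusion_reason"],
                recurrence_date=date.fromisoformat(d["recurrence_date"])
                if d["recurrence_date"]
                else None,
                recurrence_timing=d["recurrence_timing"],
                tmab_group=d["tmab_group"],
                lines=[
                    TruthLine(
                        l["line_index"],
                        date.fromisoformat(l["start"]),
                        date.fromisoformat(l["last_admin"]),
                        l["regimen_label"],
                        l["end_reason"],
                        l["event_observed"],
                    )
                    for l in d["lines"]
                ],
            )
        return cls(patients)


# -- internals ----------------------------------------------------------------


def _uniform_days(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(rng.integers(lo, hi + 1))


def _draw(rng: np.random.Generator, mix: dict[str, float]) -> str:
    labels = sorted(mix)
    probs = np.array([mix[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    return str(rng.choice(labels, p=probs))


def _cycle_dates(
    rng: np.random.Generator,
    start: date,
    duration_days: int,
    interval: int,
    jitter: int,
) -> list[date]:
    """Administration dates from ``start`` to roughly ``start+duration``;
    all consecutive gaps stay in [max(4, interval-jitter), interval+jitter]."""
    dates = [start]
    cur = start
    end = start + timedelta(days=duration_days)
    while True:
        step = interval + _uniform_days(rng, -jitter, jitter)
        step = max(4, step)
        nxt = cur + timedelta(days=step)
        if nxt > end:
            break
        dates.append(nxt)
        cur = nxt
    return dates


class _PatientBuilder:
    """Assembles one patient's events and the matching truth record."""

    def __init__(self, pid, rng, params, config, catalog):
        self.pid = pid
        self.rng = rng
        self.params = params
        self.config = config
        self.catalog = catalog
        self.prescriptions: list[PrescriptionRecord] = []
        self.diagnoses: list[DiagnosisRecord] = []
        self.procedures: list[ProcedureRecord] = []

    def rx(self, agent: str, when: date) -> None:
        self.prescriptions.append(PrescriptionRecord(self.pid, when, agent))

    def dx(self, code: str, when: date) -> None:
        cat = self.config.diagnosis_code_map.get(code, "other")
        self.diagnoses.append(DiagnosisRecord(self.pid, when, code, cat))

    def px(self, code: str, when: date) -> None:
        flags = self.config.procedure_code_map.get(code, {})
        self.procedures.append(
            ProcedureRecord(
                self.pid,
                when,
                code,
                bool(flags.get("is_gc_resection")),
                bool(flags.get("is_trial_participation")),
            )
        )

    def give_regimen(self, label: str, dates: list[date], tmab_dates=()) -> None:
        agents = sorted(self.catalog.regimen_by_label(label).agents)
        for d in dates:
            for a in agents:
                self.rx(a, d)
        for d in tmab_dates:
            self.rx("trastuzumab", d)


def _simulate_patient(
    pid: str,
    rng: np.random.Generator,
    params: SimulationParams,
    config: StudyConfig,
    catalog: RegimenCatalog,
) -> tuple[PatientRecord, _PatientBuilder, TruthPatient]:
    p = params
    b = _PatientBuilder(pid, rng, p, config, catalog)
    study_lo, study_hi = config.study_window
    margin = p.margin_days
    gap_days = config.line_gap_days
    el_thr = config.early_late_threshold_days
    # offsets bracketing the active thresholds, margin-safe by construction
    na_lo, na_hi = 30, gap_days - margin - 1  # new-agent transition window
    gp_lo, gp_hi = gap_days + margin + 1, gap_days + 100  # gap transition window
    early_hi = el_thr - margin - 1
    late_lo = el_thr + margin + 1

    neg_probs = p.negative_case_probs
    reasons = sorted(neg_probs)
    u = rng.random()
    negative: str | None = None
    acc = 0.0
    for r in reasons:
        acc += neg_probs[r]
        if u < acc:
            negative = r
            break

    era = int(rng.choice([1, 2, 3], p=np.array(p.era_weights) / sum(p.era_weights)))
    adj_regimen = _draw(rng, p.era_regimen_mix[era])
    adj_agents = set(catalog.regimen_by_label(adj_regimen).agents)

    if negative == "no_resection_within_60d":
        rs_off = _uniform_days(rng, 75, 120)
    else:
        rs_off = _uniform_days(rng, 7, 53)
    as_off = _uniform_days(rng, 14, 76)

    era_lo, era_hi = config.era_boundaries[era - 1]
    lo = max(era_lo, config.adjuvant_enrollment_start)
    hi = min(era_hi, study_hi - timedelta(days=430))
    if negative == "pre_surgery_antitumor_agent":
        lo = lo + timedelta(days=300)
    adj_start = lo + timedelta(days=_uniform_days(rng, 0, (hi - lo).days))
    resection = adj_start - timedelta(days=as_off)
    gc_dx = resection - timedelta(days=rs_off)

    b.dx("GC", gc_dx)
    b.px("GC_RESECTION", resection)

    # adjuvant administrations
    interval = p.cycle_interval_days.get(adj_regimen, p.cycle_interval_days["default"])
    if negative == "short_adjuvant":
        adj_dates = [adj_start, adj_start + timedelta(days=14)]
    elif p.adversarial:
        # one intra-line gap exactly at the end-of-line threshold: under the
        # inclusive convention the line continues
        adj_dates = [
            adj_start,
            adj_start + timedelta(days=config.line_gap_days),
            adj_start + timedelta(days=config.line_gap_days + 21),
        ]
    else:
        mu, sd = p.adjuvant_duration_months.get(adj_regimen, (9.0, 2.0))
        dur_m = float(np.clip(rng.normal(mu, sd), 4.5, 13.0))
        adj_dates = _cycle_dates(
            rng, adj_start, int(dur_m * DAYS_PER_MONTH), interval, p.gap_jitter_days
        )
    b.give_regimen(adj_regimen, adj_dates)
    adj_end = adj_dates[-1]
    last_admin = adj_end

    # deliberate rule violations
    if negative == "pre_surgery_antitumor_agent":
        b.rx("paclitaxel", resection - timedelta(days=150))
    elif negative == "non_adjuvant_agent_post_surgery":
        b.rx("irinotecan", adj_start + timedelta(days=_uniform_days(rng, 7, 48)))
    elif negative == "recurrence_before_adjuvant_end":
        mid = adj_start + timedelta(days=(adj_end - adj_start).days // 2)
        b.dx("REC", mid)
    elif negative == "trial_participation":
        b.px("TRIAL_ENTRY", resection + timedelta(days=_uniform_days(rng, 10, 60)))

    # patient-level attributes
    if negative == "age":
        birth = (adj_start.year - 19, adj_start.month)
    else:
        age = int(np.clip(rng.normal(69.0, 10.0), 25, 90))
        birth = (adj_start.year - age, _uniform_days(rng, 1, 12))
    sex = "male" if rng.random() < 0.69 else "female"
    adl_kind = _draw(rng, {"independent": 0.55, "dependent": 0.12, "missing": 0.33})
    items = ["independent"] * 10
    if adl_kind != "independent":
        items[_uniform_days(rng, 0, 9)] = "dependent" if adl_kind == "dependent" else "missing"

    # comorbidity codes in the adjuvant lookback window
    for code, prev in COMORBIDITY_PREVALENCE.items():
        if rng.random() < prev:
            when = adj_start - timedelta(days=_uniform_days(rng, 0, config.lookback_days))
            if when >= study_lo:
                b.dx(code, when)
    # occasionally a comorbidity outside the window (must not flag)
    if rng.random() < 0.10:
        when = adj_start - timedelta(days=_uniform_days(rng, 200, 400))
        if when >= study_lo:
            b.dx("CM_HYPERTENSION", when)

    # -- post-recurrent phase --------------------------------------------
    recurrence_date: date | None = None
    timing: str | None = None
    her2 = False
    post_lines: list[tuple[str, list[date], list[date], int | None]] = []
    # (label, base dates, tmab dates, offset_to_next or None)

    eligible_for_recurrence = negative in (None, "short_adjuvant")
    want_recurrence = eligible_for_recurrence and (
        negative == "short_adjuvant" or rng.random() < p.p_recurrence
    )

    if want_recurrence:
        her2 = rng.random() < p.p_her2
        early = rng.random() < p.early_weight
        if her2:
            mix_1l = p.her2_1l_mix
        else:
            mix_1l = p.early_1l_mix if early else p.late_1l_mix
        label_1l = _draw(rng, mix_1l)
        agents_1l = set(catalog.regimen_by_label(label_1l).agents)

        if p.adversarial:
            offset = el_thr if early else el_thr + 1
        elif negative == "short_adjuvant":
            offset = _uniform_days(rng, gp_lo, early_hi)
        elif early:
            if agents_1l & adj_agents:
                offset = _uniform_days(rng, gp_lo, early_hi)
            elif rng.random() < 0.5:
                offset = _uniform_days(rng, na_lo, na_hi)
            else:
                offset = _uniform_days(rng, gp_lo, early_hi)
        else:
            offset = _uniform_days(rng, late_lo, late_lo + 255)

        start_1l = adj_end + timedelta(days=offset)
        if start_1l + timedelta(days=61) <= study_hi:
            recurrence_date = adj_end + timedelta(
                days=_uniform_days(rng, 1, max(1, min(offset - 1, 60)))
            )
            b.dx("REC", recurrence_date)
            timing = "early" if offset <= el_thr else "late"

            # build lines forward; stop when the study window runs out
            level = 1
            label = label_1l
            start = start_1l
            while True:
                if level == 1:
                    dur_m = float(np.clip(rng.normal(4.8, 2.0), 2.2, 9.0))
                    intv = 14
                elif level == 2:
                    dur_m = float(np.clip(rng.normal(3.5, 1.5), 2.2, 7.0))
                    intv = 14
                else:
                    dur_m = float(np.clip(rng.normal(3.0, 1.5), 2.2, 6.0))
                    intv = 14
                dur_d = min(int(dur_m * DAYS_PER_MONTH), (study_hi - start).days)
                if dur_d < 61:
                    break
                dates = _cycle_dates(rng, start, dur_d, intv, p.gap_jitter_days)
                tmab_dates = []
                if her2 and level == 1 and len(dates) >= 2:
                    tmab_dates = dates[1::2]
                post_lines.append((label, dates, list(tmab_dates), None))
                last = dates[-1]

                if level >= 3 or rng.random() >= p.line_transition_probs[
                    min(level - 1, len(p.line_transition_probs) - 1)
                ]:
                    break
                nxt_mix = p.mix_2l if level == 1 else p.mix_3l
                nxt_label = _draw(rng, nxt_mix)
                nxt_agents = set(catalog.regimen_by_label(nxt_label).agents)
                cur_agents = set(catalog.regimen_by_label(label).agents)
                span = (last - dates[0]).days
                can_new_agent = not (nxt_agents & cur_agents) and span >= (
                    config.combination_window_days - na_lo + margin + 1
                )
                if can_new_agent and rng.random() < 0.5:
                    off_lo = max(na_lo, config.combination_window_days + margin + 1 - span)
                    off = _uniform_days(rng, off_lo, na_hi)
                else:
                    off = _uniform_days(rng, gp_lo, gp_hi)
                nxt_start = last + timedelta(days=off)
                if nxt_start + timedelta(days=61) > study_hi:
                    break
                post_lines[-1] = (label, dates, list(tmab_dates), off)
                label, start, level = nxt_label, nxt_start, level + 1

            for label_i, dates_i, tmab_i, _ in post_lines:
                b.give_regimen(label_i, dates_i, tmab_i)
            if post_lines:
                last_admin = post_lines[-1][1][-1]
            # metastasis codes in the 1L lookback window
            for code, prev in METASTASIS_PREVALENCE.items():
                if rng.random() < prev:
                    when = start_1l - timedelta(
                        days=_uniform_days(rng, 0, config.lookback_days)
                    )
                    if when >= study_lo:
                        b.dx(code, when)

    # -- follow-up after the last administration ---------------------------
    death_date: date | None = None
    room = (study_hi - last_admin).days
    mode: str
    if rng.random() < p.p_death_after_last_line and room >= 5:
        mode = "death"
        death_date = last_admin + timedelta(days=_uniform_days(rng, 5, min(60, room)))
        last_record = min(
            death_date + timedelta(days=_uniform_days(rng, 0, 20)), study_hi
        )
    elif room >= gp_lo and rng.random() < p.p_event_follow_up:
        mode = "event"
        last_record = last_admin + timedelta(
            days=_uniform_days(rng, gp_lo, min(gap_days + 200, room))
        )
    else:
        mode = "censored"
        last_record = last_admin + timedelta(
            days=_uniform_days(rng, 0, min(gap_days - margin - 1, room))
        )

    # diagnoses may not postdate the last record
    b.diagnoses = [d for d in b.diagnoses if d.date <= last_record]

    patient = PatientRecord(
        patient_id=pid,
        sex=sex,
        birth_year_month=birth,
        death_date=death_date,
        last_record_date=last_record,
        hospital_is_designated_cancer=bool(rng.random() < 0.79),
        hospital_departments=frozenset(
            ["surgery"] + (["internal_medicine"] if rng.random() < 0.15 else [])
        ),
        hospital_bed_band=_draw(rng, {"<200": 0.05, "200-<500": 0.54, ">=500": 0.41}),
        adl_items=tuple(items),
    )

    # -- truth ------------------------------------------------------------
    def final_reason() -> tuple[str, bool]:
        if mode == "death":
            return "death", True
        if mode == "event":
            return "gap_elapsed", True
        return "censored", False

    in_adjuvant = negative not in ADJUVANT_NEGATIVES
    truth_lines: list[TruthLine] = []
    if in_adjuvant:
        if post_lines:
            first_off = (post_lines[0][1][0] - adj_end).days
            adj_reason = "new_agent" if first_off <= gap_days else "gap_elapsed"
            adj_event = True
        else:
            adj_reason, adj_event = final_reason()
        truth_lines.append(
            TruthLine(0, adj_dates[0], adj_end, adj_regimen, adj_reason, adj_event)
        )
        for i, (label_i, dates_i, tmab_i, off) in enumerate(post_lines, start=1):
            disp = f"{label_i} + T-mab" if tmab_i else label_i
            if off is not None:
                reason = "new_agent" if off <= gap_days else "gap_elapsed"
                event = True
            else:
                reason, event = final_reason()
            truth_lines.append(
                TruthLine(i, dates_i[0], dates_i[-1], disp, reason, event)
            )

    in_recurrent = False
    rec_reason: str | None = None
    truth_timing: str | None = None
    truth_tmab: str | None = None
    if in_adjuvant:
        if recurrence_date is None:
            rec_reason = "no_recurrence_after_adjuvant"
        elif not post_lines:
            rec_reason = "no_post_recurrent_line"
        elif negative == "short_adjuvant":
            rec_reason = "short_adjuvant"
        else:
            w_lo, w_hi = config.recurrent_1l_window
            start_1l_actual = post_lines[0][1][0]
            if not (w_lo <= start_1l_actual <= w_hi):
                rec_reason = "first_line_outside_window"
            else:
                in_recurrent = True
                truth_timing = timing
                truth_tmab = (
                    "tmab_pos" if any(t for _, _, t, _ in post_lines) else "tmab_neg"
                )

    truth = TruthPatient(
        patient_id=pid,
        in_adjuvant=in_adjuvant,
        adjuvant_exclusion_reason=None if in_adjuvant else negative,
        adjuvant_regimen=adj_regimen if in_adjuvant else None,
        era=assign_era(adj_start, config) if in_adjuvant else None,
        in_recurrent=in_recurrent,
        recurrent_exclusion_reason=rec_reason,
        recurrence_date=recurrence_date if in_adjuvant else None,
        recurrence_timing=truth_timing,
        tmab_group=truth_tmab,
        lines=truth_lines,
    )
    return patient, b, truth


def simulate_cohort(
    params: SimulationParams,
    config: StudyConfig | None = None,
    catalog: RegimenCatalog | None = None,
) -> tuple[ClaimsBundle, GroundTruth]:
    """Generate a reproducible claims bundle plus its ground truth.

    Identical (params, seed) produce identical bundles; the ground truth is
    exact under the generating config thanks to the margin construction.
    """
    config = config or StudyConfig()
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(params.seed)
    patients: dict[str, PatientRecord] = {}
    rx, dx, px = [], [], []
    truths: dict[str, TruthPatient] = {}
    width = max(4, len(str(params.n_patients)))
    for i in range(params.n_patients):
        pid = f"P{i + 1:0{width}d}"
        patient, builder, truth = _simulate_patient(pid, rng, params, config, catalog)
        patients[pid] = patient
        rx.extend(builder.prescriptions)
        dx.extend(builder.diagnoses)
        px.extend(builder.procedures)
        truths[pid] = truth
    bundle = ClaimsBundle(patients, rx, dx, px)
    return bundle, GroundTruth(truths)
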