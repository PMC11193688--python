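"""Adjuvant and recurrent cohort derivation with strata.

The adjuvant cohort is built rule-by-rule, in a fixed documented order, and
every patient not included carries exactly one ``exclusion_reason`` — the
first failing rule — so that an attrition flow diagram can be reconstructed
from per-reason counts.

Inclusion order (adjuvant cohort):
  a. ``no_gc_diagnosis``          — no gastric-cancer diagnosis on record
  b. ``no_resection_within_60d``  — no GC resection within 60 days of the
                                    earliest GC diagnosis
  c. ``no_adjuvant_within_90d``   — no guideline adjuvant regimen starting
                                    within 90 days of the last resection
  d. ``age``                      — under 20 at adjuvant start
  e. ``before_enrollment_start``  — adjuvant start before enrollment opens
Exclusion order (after inclusion):
  1. ``non_adjuvant_agent_post_surgery``
  2. ``recurrence_before_adjuvant_end``
  3. ``pre_surgery_antitumor_agent``
  4. ``trial_participation``

The recurrent cohort is the subset of the adjuvant cohort with a recurrence
record strictly after the last adjuvant administration and a qualifying
post-recurrent first line inside the enrollment window; reasons:
``no_recurrence_after_adjuvant``, ``no_post_recurrent_line``,
``short_adjuvant`` (≤ 21 days of adjuvant prescription record),
``no_qualifying_first_line``, ``first_line_outside_window``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

from .catalog import RegimenCatalog
from .config import StudyConfig
from .lines import TreatmentLine
from .records import ClaimsBundle, DiagnosisRecord, PatientRecord

ADJUVANT_RULE_ORDER = (
    "no_gc_diagnosis",
    "no_resection_within_60d",
    "no_adjuvant_within_90d",
    "age",
    "before_enrollment_start",
    "non_adjuvant_agent_post_surgery",
    "recurrence_before_adjuvant_end",
    "pre_surgery_antitumor_agent",
    "trial_participation",
)

RECURRENT_RULE_ORDER = (
    "no_recurrence_after_adjuvant",
    "no_post_recurrent_line",
    "short_adjuvant",
    "no_qualifying_first_line",
    "first_line_outside_window",
)


@dataclass
class CohortRecord:
    patient_id: str
    included: bool = False
    exclusion_reason: str | None = None
    initial_gc_diagnosis_date: date | None = None
    last_resection_date: date | None = None
    adjuvant_start_date: date | None = None
    adjuvant_end_date: date | None = None
    adjuvant_span_days: int | None = None
    adjuvant_regimen: str | None = None
    era: int | None = None
    age_at_adjuvant_start: int | None = None
    age_group: str | None = None
    adl_status: str | None = None
    lookback_flags: dict[str, bool] = field(default_factory=dict)
    recurrence_date: date | None = None
    first_line_start_date: date | None = None
    recurrence_timing: str | None = None  # early | late
    tmab_group: str | None = None  # tmab_neg | tmab_pos
    post_recurrent_lines: list[TreatmentLine] = field(default_factory=list)
    adjuvant_line: TreatmentLine | None = None


# -- small classifiers ------------------------------------------------------


def classify_recurrence_timing(
    adjuvant_end: date, first_line_start: date, threshold_days: int
) -> str:
    """Early iff post-recurrent first-line starts at most ``threshold_days``
    after the last adjuvant administration, late otherwise."""
    if adjuvant_end is None or first_line_start is None:
        raise ValueError("both dates are required")
    if threshold_days <= 0:
        raise ValueError("threshold must be positive")
    return "early" if (first_line_start - adjuvant_end).days <= threshold_days else "late"


def tmab_group(lines: list[TreatmentLine], catalog: RegimenCatalog) -> str:
    """``tmab_pos`` iff any line's full agent set contains a HER2 antibody."""
    for line in lines:
        if any(catalog.is_tmab(c) for c in line.full_agent_set):
            return "tmab_pos"
    return "tmab_neg"


def adl_status(items: tuple[str, ...] | list[str]) -> str:
    """Barthel ADL classification: dependent if any of the 10 items is
    dependent, independent if all 10 are independent, missing otherwise."""
    if len(items) != 10:
        raise ValueError("exactly 10 ADL items required")
    if any(i == "dependent" for i in items):
        return "dependent"
    if all(i == "independent" for i in items):
        return "independent"
    return "missing"


def lookback_flags(
    diagnoses: list[DiagnosisRecord],
    index_date: date,
    config: StudyConfig,
    prefixes: tuple[str, ...] = ("comorbidity", "metastasis"),
) -> dict[str, bool]:
    """Named booleans: one flag per mapped comorbidity/metastasis category,
    true iff a matching diagnosis falls in the ``lookback_days`` window
    ending at ``index_date`` (inclusive on both sides)."""
    lo = index_date - timedelta(days=config.lookback_days)
    flags = {
        cat.split(":", 1)[1]: False
        for cat in sorted(set(config.diagnosis_code_map.values()))
        if cat.split(":", 1)[0] in prefixes
    }
    for d in diagnoses:
        head, _, name = d.category.partition(":")
        if head in prefixes and name and lo <= d.date <= index_date:
            flags[name] = True
    return flags


def assign_era(adjuvant_start: date, config: StudyConfig) -> int:
    for idx, (lo, hi) in enumerate(config.era_boundaries, start=1):
        if lo <= adjuvant_start <= hi:
            return idx
    raise ValueError(f"{adjuvant_start} falls outside every configured era")


def age_group(age_years: int, config: StudyConfig) -> str:
    lo, hi = config.age_breaks
    if age_years < lo:
        return f"<{lo}"
    if age_years < hi:
        return f"{lo}-{hi - 1}"
    return f">={hi}"


# -- adjuvant cohort ----------------------------------------------------------


def build_adjuvant_cohort(
    bundle: ClaimsBundle,
    lines_per_patient: dict[str, list[TreatmentLine]],
    catalog: RegimenCatalog,
    config: StudyConfig,
) -> list[CohortRecord]:
    """Derive the adjuvant cohort; returns one CohortRecord per patient in
    the bundle (included or carrying its first failing rule)."""
    out: list[CohortRecord] = []
    for pid, patient, rx, dx, px in bundle.grouped():
        rec = CohortRecord(patient_id=pid)
        out.append(rec)
        lines = lines_per_patient.get(pid, [])

        gc_dx = [d.date for d in dx if d.category == "gastric_cancer"]
        if not gc_dx:
            rec.exclusion_reason = "no_gc_diagnosis"
            continue
        rec.initial_gc_diagnosis_date = min(gc_dx)

        resections = sorted(p.date for p in px if p.is_gc_resection)
        valid_resections = [
            r
            for r in resections
            if 0 <= (r - rec.initial_gc_diagnosis_date).days
            <= config.surgery_after_diagnosis_days
        ]
        if not valid_resections:
            rec.exclusion_reason = "no_resection_within_60d"
            continue

        # adjuvant therapy start: first post-surgery administration of any
        # non-HER2-antibody catalog agent (prescription-anchored, so a
        # pre-surgery administration merging into the same segmented line
        # cannot mask the entry date)
        first_res = min(resections)
        post_rx = [
            r for r in rx if r.date >= first_res and not catalog.is_tmab(r.agent_code)
        ]
        if not post_rx:
            rec.exclusion_reason = "no_adjuvant_within_90d"
            continue
        adj_start = post_rx[0].date
        last_res = max(r for r in resections if r <= adj_start)
        adj_line = next(
            (l for l in lines if l.start_date <= adj_start <= l.last_admin_date), None
        )
        if (
            (adj_start - last_res).days > config.adjuvant_after_surgery_days
            or adj_line is None
        ):
            rec.exclusion_reason = "no_adjuvant_within_90d"
            continue
        reg = catalog.largest_subset_regimen(adj_line.agent_set, "adjuvant")
        if reg is None:
            rec.exclusion_reason = "no_adjuvant_within_90d"
            continue
        adj_label = reg.label
        rec.last_resection_date = last_res
        rec.adjuvant_start_date = adj_start
        rec.adjuvant_end_date = adj_line.last_admin_date
        rec.adjuvant_span_days = (adj_line.last_admin_date - adj_start).days
        rec.adjuvant_regimen = adj_label
        rec.adjuvant_line = adj_line

        rec.age_at_adjuvant_start = patient.age_at(adj_start)
        if rec.age_at_adjuvant_start < config.min_age_years:
            rec.exclusion_reason = "age"
            continue
        if adj_start < config.adjuvant_enrollment_start:
            rec.exclusion_reason = "before_enrollment_start"
            continue

        # exclusion 1: any catalog agent outside the adjuvant regimen either
        # prescribed within 90 days after surgery (HER2 antibodies included)
        # or first administered post-surgery and joining the adjuvant line
        window_hi = last_res + timedelta(days=config.adjuvant_after_surgery_days)
        extra_rx = any(
            last_res <= r.date <= window_hi and r.agent_code not in reg.agents
            for r in rx
        )
        first_admin = {}
        for r in rx:
            first_admin.setdefault(r.agent_code, r.date)
        extra_line = any(
            first_admin[a] >= last_res
            for a in adj_line.agent_set - reg.agents
        )
        if extra_rx or extra_line:
            rec.exclusion_reason = "non_adjuvant_agent_post_surgery"
            continue

        # exclusion 2: recurrence on/before the last adjuvant administration
        rec_dx = sorted(d.date for d in dx if d.category == "recurrence")
        if any(d <= adj_line.last_admin_date for d in rec_dx):
            rec.exclusion_reason = "recurrence_before_adjuvant_end"
            continue

        # exclusion 3: antitumor agent before surgery
        pre = [r for r in rx if r.date < last_res]
        if config.exclude_any_presurgery_agent:
            offending = pre
        else:
            in_regimens = set().union(*(r.agents for r in catalog.regimens))
            offending = [r for r in pre if r.agent_code not in in_regimens]
        if offending:
            rec.exclusion_reason = "pre_surgery_antitumor_agent"
            continue

        # exclusion 4: clinical-trial participation after surgery
        if any(p.is_trial_participation and p.date >= last_res for p in px):
            rec.exclusion_reason = "trial_participation"
            continue

        rec.included = True
        rec.era = assign_era(adj_line.start_date, config)
        rec.age_group = age_group(rec.age_at_adjuvant_start, config)
        rec.adl_status = adl_status(patient.adl_items)
        rec.lookback_flags = lookback_flags(
            dx, adj_line.start_date, config, prefixes=("comorbidity",)
        )
        if rec_dx:
            rec.recurrence_date = rec_dx[0]
    return out


# -- recurrent cohort ---------------------------------------------------------


def build_recurrent_cohort(
    adjuvant_cohort: list[CohortRecord],
    bundle: ClaimsBundle,
    lines_per_patient: dict[str, list[TreatmentLine]],
    catalog: RegimenCatalog,
    config: StudyConfig,
) -> list[CohortRecord]:
    """Derive the recurrent cohort from adjuvant-cohort members.

    Returns one CohortRecord per adjuvant-cohort member (included in the
    recurrent cohort, or carrying its first failing recurrent-cohort rule).
    Included members carry early/late recurrence class, HER2-antibody
    history group, post-recurrent lines renumbered 1L.., and metastasis
    lookback flags indexed at first-line start.
    """
    lo, hi = config.recurrent_1l_window
    out: list[CohortRecord] = []
    dx_by_pid: dict[str, list[DiagnosisRecord]] = {}
    for d in bundle.diagnoses:
        dx_by_pid.setdefault(d.patient_id, []).append(d)

    for adj in adjuvant_cohort:
        if not adj.included:
            continue
        rec = CohortRecord(
            patient_id=adj.patient_id,
            initial_gc_diagnosis_date=adj.initial_gc_diagnosis_date,
            last_resection_date=adj.last_resection_date,
            adjuvant_start_date=adj.adjuvant_start_date,
            adjuvant_end_date=adj.adjuvant_end_date,
            adjuvant_span_days=adj.adjuvant_span_days,
            adjuvant_regimen=adj.adjuvant_regimen,
            era=adj.era,
            adjuvant_line=adj.adjuvant_line,
        )
        out.append(rec)
        dx = dx_by_pid.get(adj.patient_id, [])
        rec_dates = sorted(
            d.date for d in dx if d.category == "recurrence"
        )
        after = [d for d in rec_dates if d > adj.adjuvant_end_date]
        if not after:
            rec.exclusion_reason = "no_recurrence_after_adjuvant"
            continue
        rec.recurrence_date = after[0]

        lines = lines_per_patient.get(adj.patient_id, [])
        post = [l for l in lines if l.start_date > adj.adjuvant_line.start_date]
        if not post:
            rec.exclusion_reason = "no_post_recurrent_line"
            continue
        first = post[0]

        if adj.adjuvant_span_days <= config.min_adjuvant_prescription_days:
            rec.exclusion_reason = "short_adjuvant"
            continue

        base = catalog.exact_regimen(first.agent_set)
        if base is None or not (
            {"first_line", "second_line"} & set(base.settings)
        ):
            rec.exclusion_reason = "no_qualifying_first_line"
            continue
        if not (lo <= first.start_date <= hi):
            rec.exclusion_reason = "first_line_outside_window"
            continue

        rec.included = True
        rec.first_line_start_date = first.start_date
        rec.recurrence_timing = classify_recurrence_timing(
            adj.adjuvant_end_date, first.start_date, config.early_late_threshold_days
        )
        rec.post_recurrent_lines = [
            TreatmentLine(**{**l.__dict__, "line_index": i})
            for i, l in enumerate(post, start=1)
        ]
        rec.tmab_group = tmab_group(rec.post_recurrent_lines, catalog)
        patient: PatientRecord = bundle.patients[adj.patient_id]
        rec.age_at_adjuvant_start = patient.age_at(first.start_date)
        rec.age_group = age_group(rec.age_at_adjuvant_start, config)
        rec.adl_status = adl_status(patient.adl_items)
        rec.lookback_flags = lookback_flags(dx, first.start_date, config)
    return out


def exclusion_flow(
    cohort: list[CohortRecord], rule_order: tuple[str, ...]
) -> list[tuple[str, int]]:
    """(rule, count) pairs in evaluation order plus the included count —
    the attrition-diagram accounting."""
    counts = {r: 0 for r in rule_order}
    included = 0
    for rec in cohort:
        if rec.included:
            included += 1
        elif rec.exclusion_reason in counts:
            counts[rec.exclusion_reason] += 1
    rows = [(r, counts[r]) for r in rule_order]
    rows.append(("included", included))
    return rows
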