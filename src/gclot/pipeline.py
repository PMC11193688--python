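"""End-to-end orchestration: segmentation → cohorts → outcome tables.

Also hosts the ground-truth verifier used to validate the pipeline against
the synthetic generator's known labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .catalog import FLUORO_OXALIPLATIN_ROLLUP, RegimenCatalog
from .cohorts import (
    ADJUVANT_RULE_ORDER,
    RECURRENT_RULE_ORDER,
    CohortRecord,
    build_adjuvant_cohort,
    build_recurrent_cohort,
    exclusion_flow,
)
from .config import StudyConfig
from .io import write_results
from .lines import TreatmentLine, segment_lines
from .records import ClaimsBundle
from .simulate import GroundTruth

log = logging.getLogger("gclot")


@dataclass
class PipelineResult:
    lines_per_patient: dict[str, list[TreatmentLine]]
    adjuvant_cohort: list[CohortRecord]
    recurrent_cohort: list[CohortRecord]
    config: StudyConfig


def run_pipeline(
    bundle: ClaimsBundle, catalog: RegimenCatalog, config: StudyConfig
) -> PipelineResult:
    """Segment every patient's lines and derive both cohorts."""
    lines_per_patient: dict[str, list[TreatmentLine]] = {}
    for pid, patient, rx, _, _ in bundle.grouped():
        lines_per_patient[pid] = segment_lines(rx, catalog, config, patient)
    log.info("segmented lines for %d patients", len(lines_per_patient))

    adjuvant = build_adjuvant_cohort(bundle, lines_per_patient, catalog, config)
    n_adj = sum(1 for r in adjuvant if r.included)
    log.info("adjuvant cohort: %d / %d patients", n_adj, len(adjuvant))

    recurrent = build_recurrent_cohort(adjuvant, bundle, lines_per_patient, catalog, config)
    n_rec = sum(1 for r in recurrent if r.included)
    log.info("recurrent cohort: %d / %d adjuvant members", n_rec, len(recurrent))
    return PipelineResult(lines_per_patient, adjuvant, recurrent, config)


# -- result tables -----------------------------------------------------------


def cohort_frame(cohort: list[CohortRecord]) -> pd.DataFrame:
    rows = []
    for r in cohort:
        rows.append(
            {
                "patient_id": r.patient_id,
                "included": r.included,
                "exclusion_reason": r.exclusion_reason or "",
                "adjuvant_start": r.adjuvant_start_date or "",
                "adjuvant_end": r.adjuvant_end_date or "",
                "adjuvant_regimen": r.adjuvant_regimen or "",
                "era": r.era or "",
                "age_group": r.age_group or "",
                "adl_status": r.adl_status or "",
                "recurrence_date": r.recurrence_date or "",
                "first_line_start": r.first_line_start_date or "",
                "recurrence_timing": r.recurrence_timing or "",
                "tmab_group": r.tmab_group or "",
            }
        )
    return pd.DataFrame(rows)


def lines_frame(lines_per_patient: dict[str, list[TreatmentLine]]) -> pd.DataFrame:
    rows = []
    for pid in sorted(lines_per_patient):
        for l in lines_per_patient[pid]:
            rows.append(
                {
                    "patient_id": pid,
                    "line_index": l.line_index,
                    "start": l.start_date,
                    "last_admin": l.last_admin_date,
                    "regimen_label": l.regimen_label,
                    "tmab_attached": l.tmab_attached,
                    "end_reason": l.end_reason,
                    "event_observed": l.event_observed,
                    "duration_days": l.duration_days(),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "line_index", "start", "last_admin", "regimen_label",
            "tmab_attached", "end_reason", "event_observed", "duration_days",
        ],
    )


def run_analysis(
    bundle: ClaimsBundle,
    catalog: RegimenCatalog,
    config: StudyConfig,
    out_dir: str | Path | None = None,
    seed: int | None = None,
    overwrite: bool = False,
) -> tuple[PipelineResult, dict[str, pd.DataFrame]]:
    """Full analysis: pipeline plus every standard result table; optionally
    written to ``out_dir`` with a manifest."""
    from .outcomes import (
        duration_table,
        pattern_by_stratum,
        sankey_extract,
        transition_table,
    )

    res = run_pipeline(bundle, catalog, config)
    adj_members = [r for r in res.adjuvant_cohort if r.included]
    rec_members = [r for r in res.recurrent_cohort if r.included]

    tables: dict[str, pd.DataFrame] = {
        "adjuvant_cohort": cohort_frame(res.adjuvant_cohort),
        "recurrent_cohort": cohort_frame(res.recurrent_cohort),
        "lines": lines_frame(res.lines_per_patient),
        "exclusion_flow": pd.DataFrame(
            [
                {"cohort": "adjuvant", "rule": rule, "count": n}
                for rule, n in exclusion_flow(res.adjuvant_cohort, ADJUVANT_RULE_ORDER)
            ]
            + [
                {"cohort": "recurrent", "rule": rule, "count": n}
                for rule, n in exclusion_flow(res.recurrent_cohort, RECURRENT_RULE_ORDER)
            ]
        ),
        "adjuvant_patterns": pattern_by_stratum(
            adj_members, "era", "adjuvant", rollup=FLUORO_OXALIPLATIN_ROLLUP
        ).rows,
        "adjuvant_patterns_by_age": pattern_by_stratum(
            adj_members, "age_group", "adjuvant"
        ).rows,
        "adjuvant_durations": duration_table(
            adj_members, bundle, config, "adjuvant", groupby=("era",)
        ),
        "first_line_patterns": pattern_by_stratum(
            [r for r in rec_members if r.tmab_group == "tmab_neg"],
            "recurrence_timing",
            "1L",
        ).rows,
        "first_line_durations": duration_table(
            rec_members, bundle, config, "first_line", groupby=("recurrence_timing",)
        ),
        "overall_durations": duration_table(
            rec_members, bundle, config, "overall",
            groupby=("recurrence_timing",), by_regimen=False,
        ),
        "transitions": transition_table(rec_members),
    }
    sankey = sankey_extract(rec_members)
    if out_dir is not None:
        write_results(
            tables,
            out_dir,
            config,
            seed=seed,
            overwrite=overwrite,
            extra_manifest={"n_patients": len(bundle.patients)},
        )
        import json

        with open(Path(out_dir) / "sankey.json", "w", encoding="utf-8") as fh:
            json.dump(sankey.to_dict(), fh, indent=1)
    return res, tables


# -- ground-truth verification -----------------------------------------------


@dataclass
class VerifyReport:
    n_patients: int
    n_matched: int
    mismatches: list[str] = field(default_factory=list)

    @property
    def all_match(self) -> bool:
        return self.n_matched == self.n_patients

    @property
    def accuracy(self) -> float:
        return self.n_matched / self.n_patients if self.n_patients else 1.0


def verify_against_truth(
    result: PipelineResult, truth: GroundTruth, bundle: ClaimsBundle
) -> VerifyReport:
    """Compare derived cohorts and lines with the generator's ground truth.

    A patient matches when cohort memberships, exclusion reasons, era,
    adjuvant regimen, early/late class, HER2-antibody group and — for
    cohort members — every line's boundaries, label, end reason and
    censoring flag agree exactly.
    """
    adj_by_pid = {r.patient_id: r for r in result.adjuvant_cohort}
    rec_by_pid = {r.patient_id: r for r in result.recurrent_cohort}
    mismatches: list[str] = []
    n = 0
    matched = 0
    for pid, t in sorted(truth.patients.items()):
        n += 1
        problems: list[str] = []
        adj = adj_by_pid.get(pid)
        if adj is None:
            problems.append("missing from adjuvant evaluation")
        else:
            if adj.included != t.in_adjuvant:
                problems.append(
                    f"adjuvant membership {adj.included} != truth {t.in_adjuvant}"
                )
            elif not t.in_adjuvant:
                if adj.exclusion_reason != t.adjuvant_exclusion_reason:
                    problems.append(
                        f"adjuvant exclusion {adj.exclusion_reason!r} != "
                        f"truth {t.adjuvant_exclusion_reason!r}"
                    )
            else:
                if adj.era != t.era:
                    problems.append(f"era {adj.era} != {t.era}")
                if adj.adjuvant_regimen != t.adjuvant_regimen:
                    problems.append(
                        f"adjuvant regimen {adj.adjuvant_regimen!r} != {t.adjuvant_regimen!r}"
                    )
                rec = rec_by_pid.get(pid)
                if rec is None:
                    problems.append("missing from recurrent evaluation")
                else:
                    if rec.included != t.in_recurrent:
                        problems.append(
                            f"recurrent membership {rec.included} != {t.in_recurrent}"
                        )
                    elif not t.in_recurrent:
                        if rec.exclusion_reason != t.recurrent_exclusion_reason:
                            problems.append(
                                f"recurrent exclusion {rec.exclusion_reason!r} != "
                                f"truth {t.recurrent_exclusion_reason!r}"
                            )
                    else:
                        if rec.recurrence_timing != t.recurrence_timing:
                            problems.append(
                                f"timing {rec.recurrence_timing} != {t.recurrence_timing}"
                            )
                        if rec.tmab_group != t.tmab_group:
                            problems.append(
                                f"tmab group {rec.tmab_group} != {t.tmab_group}"
                            )
                # line-level comparison for cohort members
                derived = []
                if adj.adjuvant_line is not None:
                    derived.append((0, adj.adjuvant_line))
                if rec is not None and rec.included:
                    derived.extend((l.line_index, l) for l in rec.post_recurrent_lines)
                truth_by_idx = {tl.line_index: tl for tl in t.lines}
                want_idx = sorted(truth_by_idx)
                got_idx = sorted(i for i, _ in derived)
                if rec is not None and rec.included and want_idx != got_idx:
                    problems.append(f"line indices {got_idx} != {want_idx}")
                for idx, line in derived:
                    tl = truth_by_idx.get(idx)
                    if tl is None:
                        continue
                    if line.start_date != tl.start:
                        problems.append(f"line {idx} start {line.start_date} != {tl.start}")
                    if line.last_admin_date != tl.last_admin:
                        problems.append(
                            f"line {idx} last_admin {line.last_admin_date} != {tl.last_admin}"
                        )
                    if line.regimen_label != tl.regimen_label:
                        problems.append(
                            f"line {idx} label {line.regimen_label!r} != {tl.regimen_label!r}"
                        )
                    if line.end_reason != tl.end_reason:
                        problems.append(
                            f"line {idx} end {line.end_reason} != {tl.end_reason}"
                        )
                    if line.event_observed != tl.event_observed:
                        problems.append(
                            f"line {idx} event {line.event_observed} != {tl.event_observed}"
                        )
        if problems:
            mismatches.append(f"{pid}: " + "; ".join(problems))
        else:
            matched += 1
    return VerifyReport(n_patients=n, n_matched=matched, mismatches=mismatches)
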