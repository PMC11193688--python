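"""Duration estimation and treatment-pattern reporting.

Kaplan–Meier fitting is delegated to ``lifelines``; the median confidence
interval comes from inverting the log–log (exponential Greenwood)
confidence band of the survivor function at 0.5, the dominant convention in
oncology reporting.  Everything else here is counting: within-stratum
regimen pattern tables, line-to-line transition rates, Sankey sequence
extraction, and the two sensitivity re-analyses (early/late threshold and
end-of-line gap).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times

from .catalog import RegimenCatalog
from .cohorts import CohortRecord, classify_recurrence_timing
from .config import MONTHS_PER_DAY, StudyConfig, round_half_up
from .lines import TreatmentLine, line_duration, overall_duration
from .records import ClaimsBundle

NOT_REACHED = float("inf")


# -- Kaplan–Meier -------------------------------------------------------------


@dataclass
class KMCurve:
    event_times: np.ndarray  # ascending, event times only
    survival: np.ndarray  # product-limit value just after each event time
    n_at_risk: np.ndarray
    median: float  # inf = not reached
    median_ci_95: tuple[float, float]
    n: int

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of the product-limit estimate."""
        s = 1.0
        for et, sv in zip(self.event_times, self.survival):
            if et <= t:
                s = sv
            else:
                break
        return s


def km_estimate(observations: list[tuple[float, bool]]) -> KMCurve:
    """Product-limit estimate of a duration endpoint.

    ``observations`` are (time, event_observed) pairs; censored entries have
    event_observed False.  Median is the smallest time with survival <= 0.5
    (infinity when never reached); the 95% CI uses the log–log transformed
    Greenwood band.
    """
    if not observations:
        raise ValueError("at least one observation required")
    times = np.asarray([t for t, _ in observations], dtype=float)
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    events = np.asarray([bool(e) for _, e in observations])

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)

    sf = kmf.survival_function_["KM_estimate"]
    ev_times = np.unique(times[events])
    surv = np.asarray([float(sf.loc[t]) for t in ev_times])
    at_risk = np.asarray(
        [int((times >= t).sum()) for t in ev_times], dtype=int
    )

    # median = smallest event time with S(t) <= 0.5 (inclusive at exactly
    # one half, the standard product-limit convention)
    median = NOT_REACHED
    for t, s in zip(ev_times, surv):
        if s <= 0.5 + 1e-12:
            median = float(t)
            break
    ci = median_survival_times(kmf.confidence_interval_)
    lo = float(ci.iloc[0, 0])
    hi = float(ci.iloc[0, 1])
    return KMCurve(
        event_times=ev_times,
        survival=surv,
        n_at_risk=at_risk,
        median=median,
        median_ci_95=(
            lo if not math.isnan(lo) else NOT_REACHED,
            hi if not math.isnan(hi) else NOT_REACHED,
        ),
        n=len(observations),
    )


def format_median(x: float) -> str:
    return "NR" if math.isinf(x) else f"{round_half_up(x, 1):.1f}"


# -- transitions --------------------------------------------------------------


def transition_rate(n_ended: int, n_next: int) -> float | None:
    """Percent of patients who, having discontinued a line or died, started
    the next line; one-decimal, half-up.  ``None`` when the denominator is
    empty (undefined)."""
    if n_ended == 0:
        return None
    if not (0 <= n_next <= n_ended):
        raise ValueError("need 0 <= n_next <= n_ended")
    return round_half_up(100.0 * n_next / n_ended, 1)


# -- pattern tables -----------------------------------------------------------


def _largest_remainder_percents(ns: list[int], total: int) -> list[float]:
    """One-decimal percentages that sum exactly to 100.0.

    Plain half-up rounding can drift by 0.05 per row; the largest-remainder
    method floors every share to 0.1 and hands the leftover tenths to the
    largest fractional remainders, so within-stratum percentages always
    total 100.0 while each entry stays within 0.1 of its exact share.
    """
    if total == 0:
        return [0.0 for _ in ns]
    exact = [1000.0 * n / total for n in ns]  # tenths of a percent
    floors = [int(x) for x in exact]
    leftover = 1000 - sum(floors)
    order = sorted(
        range(len(ns)), key=lambda i: (-(exact[i] - floors[i]), i)
    )
    for i in order[:leftover]:
        floors[i] += 1
    return [f / 10.0 for f in floors]


@dataclass
class PatternTable:
    stratifier: str
    line_level: str
    rows: pd.DataFrame  # columns: stratum, regimen, n, percent

    def stratum(self, label) -> pd.DataFrame:
        return self.rows[self.rows["stratum"] == label]


def _line_at_level(rec: CohortRecord, line_level: str) -> TreatmentLine | None:
    if line_level == "adjuvant":
        return rec.adjuvant_line
    idx = {"1L": 1, "2L": 2, "3L": 3}[line_level]
    for line in rec.post_recurrent_lines:
        if line.line_index == idx:
            return line
    return None


def pattern_by_stratum(
    cohort: list[CohortRecord],
    stratifier: str,
    line_level: str,
    rollup: dict[str, str] | None = None,
) -> PatternTable:
    """Counts and within-stratum percentages of regimen labels.

    ``stratifier`` is one of era / age_group / recurrence_timing /
    tmab_group; ``line_level`` one of adjuvant / 1L / 2L / 3L.  ``rollup``
    optionally maps regimen labels onto grouped display labels (e.g. SOX
    and CapeOX onto "Fluoropyrimidine + oxaliplatin").  Rows are ordered by
    (count desc, label asc) within stratum.
    """
    counts: dict[tuple[object, str], int] = {}
    totals: dict[object, int] = {}
    for rec in cohort:
        if not rec.included:
            continue
        stratum = getattr(rec, stratifier)
        line = _line_at_level(rec, line_level)
        if line is None:
            continue
        label = line.regimen_label
        if line_level == "adjuvant" and rec.adjuvant_regimen:
            label = rec.adjuvant_regimen
        if rollup:
            label = rollup.get(label, label)
        totals[stratum] = totals.get(stratum, 0) + 1
        counts[(stratum, label)] = counts.get((stratum, label), 0) + 1

    rows = []
    for stratum, total in totals.items():
        entries = sorted(
            ((lab, n) for (s, lab), n in counts.items() if s == stratum),
            key=lambda kv: (-kv[1], kv[0]),
        )
        pcts = _largest_remainder_percents([n for _, n in entries], total)
        for (label, n), pct in zip(entries, pcts):
            rows.append({"stratum": stratum, "regimen": label, "n": n, "percent": pct})
    df = pd.DataFrame(rows, columns=["stratum", "regimen", "n", "percent"])
    if len(df):
        df["_neg_n"] = -df["n"]
        df = (
            df.sort_values(["stratum", "_neg_n", "regimen"])
            .drop(columns="_neg_n")
            .reset_index(drop=True)
        )
    return PatternTable(stratifier=stratifier, line_level=line_level, rows=df)


# -- Sankey -------------------------------------------------------------------


@dataclass
class SankeyGraph:
    nodes: list[dict]  # {level, label, count}
    links: list[dict]  # {source_level, source, target_level, target, count}
    terminal_label: str = "no_further_line"

    def to_dict(self) -> dict:
        return {
            "nodes": self.nodes,
            "links": self.links,
            "terminal_label": self.terminal_label,
        }

    def node_count(self, level: str, label: str) -> int:
        for n in self.nodes:
            if n["level"] == level and n["label"] == label:
                return n["count"]
        return 0


def sankey_extract(
    recurrent_cohort: list[CohortRecord],
    top_k: int = 5,
    min_count: int = 1,
    max_level: int = 3,
) -> SankeyGraph:
    """Treatment-sequence graph over post-recurrent lines 1L..{max_level}L.

    Per level the ``top_k`` regimens by count become nodes (ties broken
    alphabetically); the rest collapse into "Other".  Regimens under
    ``min_count`` also collapse.  Patients without a further line flow to
    the terminal node, as does everyone after the last level, so inflow
    equals outflow at every non-terminal node.
    """
    members = [r for r in recurrent_cohort if r.included]
    levels = [f"{i}L" for i in range(1, max_level + 1)]

    # raw per-level label counts
    label_maps: dict[str, dict[str, str]] = {}
    for li, level in enumerate(levels, start=1):
        raw: dict[str, int] = {}
        for rec in members:
            line = next((l for l in rec.post_recurrent_lines if l.line_index == li), None)
            if line is not None:
                raw[line.regimen_label] = raw.get(line.regimen_label, 0) + 1
        kept = sorted(raw.items(), key=lambda kv: (-kv[1], kv[0]))
        keep = {lab for lab, n in kept[:top_k] if n >= min_count}
        label_maps[level] = {lab: (lab if lab in keep else "Other") for lab in raw}

    node_counts: dict[tuple[str, str], int] = {}
    link_counts: dict[tuple[str, str, str, str], int] = {}
    for rec in members:
        prev: tuple[str, str] | None = None
        for li, level in enumerate(levels, start=1):
            line = next((l for l in rec.post_recurrent_lines if l.line_index == li), None)
            if line is None:
                break
            label = label_maps[level][line.regimen_label]
            node_counts[(level, label)] = node_counts.get((level, label), 0) + 1
            if prev is not None:
                key = (*prev, level, label)
                link_counts[key] = link_counts.get(key, 0) + 1
            prev = (level, label)
        if prev is not None:
            # flows to terminal when no further line within the graph depth
            li = levels.index(prev[0]) + 2
            has_next = li <= max_level and any(
                l.line_index == li for l in rec.post_recurrent_lines
            )
            if not has_next:
                key = (*prev, "terminal", "no_further_line")
                link_counts[key] = link_counts.get(key, 0) + 1

    nodes = [
        {"level": lv, "label": lab, "count": n}
        for (lv, lab), n in sorted(node_counts.items())
    ]
    term_in = sum(n for (s_lv, s, t_lv, t), n in link_counts.items() if t_lv == "terminal")
    nodes.append({"level": "terminal", "label": "no_further_line", "count": term_in})
    links = [
        {"source_level": s_lv, "source": s, "target_level": t_lv, "target": t, "count": n}
        for (s_lv, s, t_lv, t), n in sorted(link_counts.items())
    ]
    return SankeyGraph(nodes=nodes, links=links)


# -- duration tables ----------------------------------------------------------


def _endpoint_observation(
    rec: CohortRecord,
    bundle: ClaimsBundle,
    config: StudyConfig,
    endpoint: str,
) -> tuple[float, bool] | None:
    patient = bundle.patients[rec.patient_id]
    if endpoint == "adjuvant":
        if rec.adjuvant_line is None:
            return None
        days, event = line_duration(rec.adjuvant_line, patient, config)
    elif endpoint == "first_line":
        line = _line_at_level(rec, "1L")
        if line is None:
            return None
        days, event = line_duration(line, patient, config)
    elif endpoint == "overall":
        if not rec.post_recurrent_lines:
            return None
        days, event = overall_duration(rec.post_recurrent_lines, patient, config)
    else:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    return days * MONTHS_PER_DAY, event


def duration_table(
    cohort: list[CohortRecord],
    bundle: ClaimsBundle,
    config: StudyConfig,
    endpoint: str,
    groupby: tuple[str, ...] = (),
    by_regimen: bool = True,
    min_count: int = 1,
) -> pd.DataFrame:
    """Kaplan–Meier medians (months, with 95% CI) per stratum and regimen.

    ``endpoint`` is adjuvant / first_line / overall; ``groupby`` names
    CohortRecord stratifiers.  Regimens with fewer than ``min_count``
    observations are pooled under their stratum total only.
    """
    endpoint_level = {"adjuvant": "adjuvant", "first_line": "1L", "overall": "1L"}[endpoint]
    buckets: dict[tuple, list[tuple[float, bool]]] = {}
    for rec in cohort:
        if not rec.included:
            continue
        obs = _endpoint_observation(rec, bundle, config, endpoint)
        if obs is None:
            continue
        stratum = tuple(getattr(rec, g) for g in groupby)
        line = _line_at_level(rec, endpoint_level)
        if endpoint == "adjuvant":
            regimen = rec.adjuvant_regimen
        else:
            regimen = line.regimen_label if line else None
        buckets.setdefault(stratum + ("All regimens",), []).append(obs)
        if by_regimen and regimen is not None:
            buckets.setdefault(stratum + (regimen,), []).append(obs)

    rows = []
    for key, obs_list in sorted(buckets.items(), key=lambda kv: tuple(map(str, kv[0]))):
        *stratum, regimen = key
        if regimen != "All regimens" and len(obs_list) < min_count:
            continue
        curve = km_estimate(obs_list)
        row = {g: s for g, s in zip(groupby, stratum)}
        row.update(
            {
                "regimen": regimen,
                "n": curve.n,
                "median_months": format_median(curve.median),
                "ci95_low": format_median(curve.median_ci_95[0]),
                "ci95_high": format_median(curve.median_ci_95[1]),
            }
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=[*groupby, "regimen", "n", "median_months", "ci95_low", "ci95_high"])


def transition_table(
    recurrent_cohort: list[CohortRecord], max_level: int = 3
) -> pd.DataFrame:
    """Line-to-line transition rates for the recurrent cohort.

    The denominator at level L counts patients whose L-line ended with an
    observed event (discontinuation or death); patients censored on their
    final line are excluded from the denominator.
    """
    rows = []
    members = [r for r in recurrent_cohort if r.included]
    for li in range(1, max_level + 1):
        ended = 0
        moved = 0
        for rec in members:
            line = next((l for l in rec.post_recurrent_lines if l.line_index == li), None)
            if line is None:
                continue
            nxt = next(
                (l for l in rec.post_recurrent_lines if l.line_index == li + 1), None
            )
            if nxt is not None:
                ended += 1
                moved += 1
            elif line.event_observed:
                ended += 1
        rate = transition_rate(ended, moved)
        rows.append(
            {
                "from_level": f"{li}L",
                "to_level": f"{li + 1}L",
                "n_ended": ended,
                "n_next": moved,
                "transition_pct": rate if rate is not None else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# -- sensitivity --------------------------------------------------------------


@dataclass
class SensitivityResult:
    label: str
    config: StudyConfig
    early_count: int
    late_count: int
    pattern_1l: PatternTable
    timing_by_patient: dict[str, str] = field(default_factory=dict)


def run_sensitivity(
    bundle: ClaimsBundle,
    catalog: RegimenCatalog,
    base_config: StudyConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, list[SensitivityResult]]:
    """Re-run the full pipeline under the base and the two sensitivity
    configurations and tabulate early/late counts, 1L patterns, and a
    patient-level reclassification list.

    Branches: (threshold 180, gap 120) — base; (threshold 210, gap 120);
    (threshold 180, gap 90).
    """
    from .pipeline import run_pipeline  # deferred import (pipeline uses outcomes)

    branches = [
        ("base_180_120", base_config),
        (
            "early_late_210",
            base_config.replace(early_late_threshold_days=210),
        ),
        ("line_gap_90", base_config.replace(line_gap_days=90)),
    ]
    results: list[SensitivityResult] = []
    for label, cfg in branches:
        res = run_pipeline(bundle, catalog, cfg)
        members = [r for r in res.recurrent_cohort if r.included]
        early = sum(1 for r in members if r.recurrence_timing == "early")
        late = sum(1 for r in members if r.recurrence_timing == "late")
        results.append(
            SensitivityResult(
                label=label,
                config=cfg,
                early_count=early,
                late_count=late,
                pattern_1l=pattern_by_stratum(members, "recurrence_timing", "1L"),
                timing_by_patient={r.patient_id: r.recurrence_timing for r in members},
            )
        )

    summary = pd.DataFrame(
        [
            {
                "branch": r.label,
                "early_late_threshold_days": r.config.early_late_threshold_days,
                "line_gap_days": r.config.line_gap_days,
                "n_recurrent": r.early_count + r.late_count,
                "n_early": r.early_count,
                "n_late": r.late_count,
            }
            for r in results
        ]
    )
    base = results[0]
    reclass_rows = []
    for r in results[1:]:
        ids = set(base.timing_by_patient) | set(r.timing_by_patient)
        for pid in sorted(ids):
            a = base.timing_by_patient.get(pid)
            b = r.timing_by_patient.get(pid)
            if a != b:
                reclass_rows.append(
                    {"branch": r.label, "patient_id": pid, "base": a, "branch_class": b}
                )
    reclass = pd.DataFrame(reclass_rows, columns=["branch", "patient_id", "base", "branch_class"])
    return summary, reclass, results
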