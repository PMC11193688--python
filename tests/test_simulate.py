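"""Synthetic claims generator: determinism, margins, calibration."""

from __future__ import annotations

import math

import numpy as np
import pytest

from gclot import SimulationParams, simulate_cohort
from gclot.simulate import DEFAULT_NEGATIVE_CASE_PROBS


def test_same_seed_reproduces_bundle_exactly(config, catalog):
    a, ta = simulate_cohort(SimulationParams(n_patients=60, seed=8), config, catalog)
    b, tb = simulate_cohort(SimulationParams(n_patients=60, seed=8), config, catalog)
    assert a.prescriptions == b.prescriptions
    assert a.diagnoses == b.diagnoses
    assert a.procedures == b.procedures
    assert {p: ta.patients[p].to_dict() for p in ta.patients} == {
        p: tb.patients[p].to_dict() for p in tb.patients
    }


def test_distinct_seeds_differ(config, catalog):
    a, _ = simulate_cohort(SimulationParams(n_patients=60, seed=8), config, catalog)
    c, _ = simulate_cohort(SimulationParams(n_patients=60, seed=9), config, catalog)
    assert a.prescriptions != c.prescriptions


def test_degenerate_single_patient_pure_s1(config, catalog):
    mix = {1: {"S-1": 1.0}, 2: {"S-1": 1.0}, 3: {"S-1": 1.0}}
    params = SimulationParams(
        n_patients=1, seed=1, p_recurrence=0.0,
        era_weights=(1.0, 0.0, 0.0), era_regimen_mix=mix,
        negative_case_probs={},
    )
    bundle, truth = simulate_cohort(params, config, catalog)
    (pid,) = bundle.patients
    t = truth.patients[pid]
    assert t.in_adjuvant and t.adjuvant_regimen == "S-1" and t.era == 1
    assert not t.in_recurrent
    # diagnosis -> resection within 60 days -> S-1 within 90 days of surgery
    gc = min(d.date for d in bundle.diagnoses if d.category == "gastric_cancer")
    resect = min(p.date for p in bundle.procedures if p.is_gc_resection)
    first_rx = min(r.date for r in bundle.prescriptions)
    assert 0 <= (resect - gc).days <= 60
    assert 0 <= (first_rx - resect).days <= 90
    assert {r.agent_code for r in bundle.prescriptions} == {"s1"}


def test_margin_property_keeps_gaps_away_from_thresholds(config, catalog):
    params = SimulationParams(n_patients=250, seed=14)
    bundle, truth = simulate_cohort(params, config, catalog)
    m = params.margin_days
    forbidden = range(config.line_gap_days - m, config.line_gap_days + m + 1)
    for pid, _, rx, _, _ in bundle.grouped():
        days = sorted({r.date for r in rx})
        for a, b in zip(days, days[1:]):
            assert (b - a).days not in forbidden, pid
    # recurrence offsets stay clear of the early/late threshold
    lo = config.early_late_threshold_days - m
    hi = config.early_late_threshold_days + m
    for pid, t in truth.patients.items():
        post = [l for l in t.lines if l.line_index == 1]
        adj = [l for l in t.lines if l.line_index == 0]
        if post and adj:
            off = (post[0].start - adj[0].last_admin).days
            assert not (lo <= off <= hi), (pid, off)


def test_early_fraction_within_three_se_of_mixture_weight(config, catalog):
    params = SimulationParams(n_patients=500, seed=42)
    bundle, truth = simulate_cohort(params, config, catalog)
    timings = [
        t.recurrence_timing for t in truth.patients.values() if t.in_recurrent
    ]
    n = len(timings)
    assert n > 50
    frac = sum(1 for x in timings if x == "early") / n
    p = params.early_weight
    se = math.sqrt(p * (1 - p) / n)
    assert abs(frac - p) <= 3 * se


def test_negative_cases_cover_every_rule(config, catalog):
    bundle, truth = simulate_cohort(
        SimulationParams(n_patients=600, seed=77), config, catalog
    )
    reasons = {
        t.adjuvant_exclusion_reason
        for t in truth.patients.values()
        if t.adjuvant_exclusion_reason
    }
    assert set(DEFAULT_NEGATIVE_CASE_PROBS) - {"short_adjuvant"} <= reasons
    assert any(
        t.recurrent_exclusion_reason == "short_adjuvant"
        for t in truth.patients.values()
    )


def test_invalid_params_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        SimulationParams(era_regimen_mix={1: {"S-1": 0.5}, 2: {"S-1": 1.0}, 3: {"S-1": 1.0}})
    with pytest.raises(ValueError, match="n_patients"):
        SimulationParams(n_patients=0)
    with pytest.raises(ValueError, match="margin_days"):
        SimulationParams(margin_days=0)
    with pytest.raises(ValueError, match="p_recurrence"):
        SimulationParams(p_recurrence=1.5)


def test_truth_json_round_trip(tmp_path, config, catalog):
    _, truth = simulate_cohort(SimulationParams(n_patients=30, seed=2), config, catalog)
    truth.to_json(tmp_path / "truth.json")
    from gclot.simulate import GroundTruth

    loaded = GroundTruth.from_json(tmp_path / "truth.json")
    assert {p: t.to_dict() for p, t in loaded.patients.items()} == {
        p: t.to_dict() for p, t in truth.patients.items()
    }


def test_all_prescriptions_inside_study_window(config, catalog):
    bundle, _ = simulate_cohort(SimulationParams(n_patients=300, seed=55), config, catalog)
    lo, hi = config.study_window
    assert all(lo <= r.date <= hi for r in bundle.prescriptions)
    for p in bundle.patients.values():
        assert p.last_record_date <= hi
        if p.death_date:
            assert p.death_date <= p.last_record_date
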