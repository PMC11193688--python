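"""Kaplan–Meier estimation, pattern tables, transitions, Sankey, sensitivity."""

from __future__ import annotations

import math

import numpy as np
import pytest
from _oracles import product_limit

from gclot import (
    SimulationParams,
    km_estimate,
    pattern_by_stratum,
    run_pipeline,
    run_sensitivity,
    sankey_extract,
    simulate_cohort,
    transition_rate,
)
from gclot.cohorts import CohortRecord
from gclot.lines import TreatmentLine
from gclot.outcomes import NOT_REACHED, transition_table
from conftest import BASE
from datetime import timedelta


def test_km_matches_hand_product_limit_example():
    # events at months 2,4,6,8,10, none censored: survival steps by 0.2
    obs = [(2.0, True), (4.0, True), (6.0, True), (8.0, True), (10.0, True)]
    curve = km_estimate(obs)
    assert curve.survival_at(6.0) == pytest.approx(0.4)
    assert curve.median == pytest.approx(6.0)
    assert list(curve.event_times) == [2.0, 4.0, 6.0, 8.0, 10.0]


def test_km_all_censored_median_not_reached():
    curve = km_estimate([(3.0, False), (5.0, False)])
    assert math.isinf(curve.median)


def test_km_single_event():
    assert km_estimate([(5.0, True)]).median == pytest.approx(5.0)


def test_km_empty_input_rejected():
    with pytest.raises(ValueError):
        km_estimate([])


def test_km_agrees_with_oracle_across_censoring_patterns():
    rng = np.random.default_rng(3)
    for _ in range(150):
        n = int(rng.integers(1, 9))
        times = [float(t) for t in rng.integers(1, 12, size=n)]
        events = [bool(b) for b in rng.integers(0, 2, size=n)]
        obs = list(zip(times, events))
        curve = km_estimate(obs)
        oracle_curve, oracle_median = product_limit(obs)
        for t, s in oracle_curve:
            assert curve.survival_at(t) == pytest.approx(s, abs=1e-9)
        if math.isinf(oracle_median):
            assert math.isinf(curve.median)
        else:
            assert curve.median == pytest.approx(oracle_median)


@pytest.mark.parametrize(
    "ended,moved,expected",
    [(596, 333, 55.9), (524, 289, 55.2), (10, 0, 0.0), (89, 73, 82.0), (34, 27, 79.4)],
)
def test_transition_rate_reproduces_worked_examples(ended, moved, expected):
    assert transition_rate(ended, moved) == pytest.approx(expected)


def test_transition_rate_edge_cases():
    assert transition_rate(0, 0) is None
    with pytest.raises(ValueError):
        transition_rate(5, 6)
    # adding one transitioning patient never decreases the rate
    for n in range(1, 30):
        rates = [transition_rate(30, k) for k in range(n + 1)]
        assert rates == sorted(rates)


def _member(pid, labels, timing="early"):
    lines = []
    d = BASE
    for i, lab in enumerate(labels, start=1):
        lines.append(
            TreatmentLine(
                patient_id=pid, line_index=i, start_date=d, last_admin_date=d + timedelta(days=90),
                agent_set=frozenset({"x"}), regimen_label=lab, end_reason="gap_elapsed",
                event_observed=True,
            )
        )
        d += timedelta(days=200)
    return CohortRecord(
        patient_id=pid, included=True, recurrence_timing=timing,
        tmab_group="tmab_neg", post_recurrent_lines=lines,
    )


def test_pattern_table_counts_and_percentages():
    cohort = [_member(f"P{i}", ["S-1"]) for i in range(13)]
    cohort += [_member(f"Q{i}", ["DS"]) for i in range(4)]
    cohort += [_member(f"R{i}", ["SOX"]) for i in range(3)]
    tab = pattern_by_stratum(cohort, "recurrence_timing", "1L")
    rows = tab.rows
    assert rows["n"].sum() == 20
    assert rows["percent"].sum() == pytest.approx(100.0, abs=0.1)
    by_label = dict(zip(rows["regimen"], rows["percent"]))
    assert by_label == {"S-1": 65.0, "DS": 20.0, "SOX": 15.0}
    # ordering: count desc, then label asc
    assert list(rows["regimen"]) == ["S-1", "DS", "SOX"]


def test_pattern_table_single_patient_stratum():
    tab = pattern_by_stratum([_member("P1", ["SP"])], "recurrence_timing", "1L")
    assert list(tab.rows["percent"]) == [100.0]


def test_sankey_hand_counted_example():
    cohort = [
        _member("A", ["SOX", "PTX + RAM"]),
        _member("B", ["SOX"]),
        _member("C", ["S-1", "PTX + RAM", "NIV"]),
    ]
    g = sankey_extract(cohort, top_k=5)
    assert g.node_count("1L", "SOX") == 2
    assert g.node_count("1L", "S-1") == 1
    links = {(l["source"], l["target"]): l["count"] for l in g.links}
    assert links[("SOX", "PTX + RAM")] == 1
    assert links[("SOX", "no_further_line")] == 1
    assert links[("PTX + RAM", "NIV")] == 1


def test_sankey_top_k_collapses_to_other():
    cohort = [_member(f"A{i}", ["SOX"]) for i in range(5)]
    cohort += [_member(f"B{i}", ["SP"]) for i in range(3)]
    g = sankey_extract(cohort, top_k=1)
    labels_1l = {n["label"] for n in g.nodes if n["level"] == "1L"}
    assert labels_1l == {"SOX", "Other"}


def _assert_conserved(graph):
    inflow = {}
    outflow = {}
    for l in graph.links:
        outflow[(l["source_level"], l["source"])] = (
            outflow.get((l["source_level"], l["source"]), 0) + l["count"]
        )
        inflow[(l["target_level"], l["target"])] = (
            inflow.get((l["target_level"], l["target"]), 0) + l["count"]
        )
    for n in graph.nodes:
        key = (n["level"], n["label"])
        if n["level"] == "terminal":
            assert inflow.get(key, 0) == n["count"]
        else:
            assert outflow.get(key, 0) == n["count"], key
            if n["level"] != "1L":
                assert inflow.get(key, 0) == n["count"]


def test_sankey_flow_conservation_on_simulated_cohort(config, catalog):
    bundle, _ = simulate_cohort(SimulationParams(n_patients=250, seed=31), config, catalog)
    res = run_pipeline(bundle, catalog, config)
    members = [r for r in res.recurrent_cohort if r.included]
    _assert_conserved(sankey_extract(members, top_k=4))


def test_transition_denominator_excludes_censored_final_lines(config, catalog):
    bundle, _ = simulate_cohort(SimulationParams(n_patients=250, seed=32), config, catalog)
    res = run_pipeline(bundle, catalog, config)
    members = [r for r in res.recurrent_cohort if r.included]
    tab = transition_table(members)
    row = tab[tab["from_level"] == "1L"].iloc[0]
    n_1l = sum(1 for r in members if r.post_recurrent_lines)
    censored_1l = sum(
        1
        for r in members
        if len(r.post_recurrent_lines) == 1 and not r.post_recurrent_lines[0].event_observed
    )
    assert row["n_ended"] == n_1l - censored_1l
    assert 0 <= row["transition_pct"] <= 100


def test_sensitivity_partitions_and_reclassification(config, catalog):
    bundle, _ = simulate_cohort(SimulationParams(n_patients=200, seed=33), config, catalog)
    summary, reclass, results = run_sensitivity(bundle, catalog, config)
    # under every threshold configuration early + late = recurrent cohort
    for _, row in summary.iterrows():
        assert row["n_early"] + row["n_late"] == row["n_recurrent"]
    # widening the threshold can only relabel late -> early (nesting), as in
    # the worked example of a first line starting 200 days post-adjuvant
    r210 = reclass[reclass["branch"] == "early_late_210"]
    assert (r210["base"] == "late").all() and (r210["branch_class"] == "early").all()
    base, t210, gap90 = results
    assert t210.early_count >= base.early_count
    # margin-safe gaps: the 90-day end-of-line rule keeps the same members
    # and the same early/late classes
    assert gap90.timing_by_patient == base.timing_by_patient


def test_km_curve_is_monotone_nonincreasing(config, catalog):
    bundle, _ = simulate_cohort(SimulationParams(n_patients=150, seed=34), config, catalog)
    res = run_pipeline(bundle, catalog, config)
    from gclot.outcomes import _endpoint_observation

    obs = []
    for r in res.recurrent_cohort:
        if r.included:
            o = _endpoint_observation(r, bundle, config, "first_line")
            if o:
                obs.append(o)
    curve = km_estimate(obs)
    assert all(a >= b for a, b in zip(curve.survival, curve.survival[1:]))
    assert curve.survival[0] <= 1.0
    if not math.isinf(curve.median):
        assert curve.survival_at(curve.median) <= 0.5
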