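"""Cohort rules, strata classifiers, and attrition accounting."""

from __future__ import annotations

from datetime import date

import pytest

from gclot import (
    SimulationParams,
    StudyConfig,
    adl_status,
    age_group,
    assign_era,
    classify_recurrence_timing,
    exclusion_flow,
    lookback_flags,
    run_pipeline,
    simulate_cohort,
    tmab_group,
)
from gclot.cohorts import ADJUVANT_RULE_ORDER, RECURRENT_RULE_ORDER
from gclot.lines import TreatmentLine
from gclot.records import DiagnosisRecord


@pytest.mark.parametrize(
    "gap,threshold,expected",
    [
        (180, 180, "early"),  # "during or <= 180 days": inclusive boundary
        (181, 180, "late"),
        (200, 210, "early"),  # sensitivity threshold
        (200, 180, "late"),
        (0, 180, "early"),
    ],
)
def test_recurrence_timing_boundaries(gap, threshold, expected):
    adj_end = date(2018, 1, 1)
    first = date(2018, 1, 1).fromordinal(adj_end.toordinal() + gap)
    assert classify_recurrence_timing(adj_end, first, threshold) == expected


def test_recurrence_timing_input_validation():
    with pytest.raises(ValueError):
        classify_recurrence_timing(None, date(2018, 1, 1), 180)
    with pytest.raises(ValueError):
        classify_recurrence_timing(date(2018, 1, 1), date(2018, 6, 1), 0)


@pytest.mark.parametrize(
    "items,expected",
    [
        (("independent",) * 10, "independent"),
        (("independent",) * 9 + ("dependent",), "dependent"),
        (("independent",) * 9 + ("missing",), "missing"),
        (("missing",) * 10, "missing"),
        (("dependent",) + ("missing",) * 9, "dependent"),  # any dependent wins
    ],
)
def test_adl_classification_truth_table(items, expected):
    assert adl_status(items) == expected


def test_adl_requires_exactly_ten_items():
    with pytest.raises(ValueError):
        adl_status(("independent",) * 9)


@pytest.mark.parametrize("age,expected", [(64, "<65"), (65, "65-74"), (74, "65-74"), (75, ">=75"), (21, "<65")])
def test_age_grouping(config, age, expected):
    assert age_group(age, config) == expected


@pytest.mark.parametrize(
    "day,expected",
    [
        (date(2008, 10, 1), 1),
        (date(2016, 5, 31), 1),
        (date(2016, 6, 1), 2),
        (date(2019, 8, 31), 2),
        (date(2019, 9, 1), 3),
        (date(2020, 1, 15), 3),
        (date(2022, 3, 31), 3),
    ],
)
def test_era_boundaries(config, day, expected):
    assert assign_era(day, config) == expected


def test_era_outside_all_intervals_is_an_error(config):
    with pytest.raises(ValueError):
        assign_era(date(2008, 9, 30), config)


def test_lookback_flags_window_is_inclusive(config):
    index = date(2018, 6, 1)

    def dx(days_before, code="CM_HYPERTENSION"):
        return DiagnosisRecord(
            "X", date.fromordinal(index.toordinal() - days_before), code,
            config.diagnosis_code_map[code],
        )

    flags = lookback_flags([dx(90)], index, config)
    assert flags["hypertension"]
    assert not lookback_flags([dx(181)], index, config)["hypertension"]
    assert lookback_flags([dx(180)], index, config)["hypertension"]
    # metastasis categories flagged relative to first-line start
    flags = lookback_flags([dx(10, "MET_PERITONEAL")], index, config)
    assert flags["peritoneal"]


def _line(agents, label, tmab=False):
    d = date(2018, 1, 1)
    return TreatmentLine(
        patient_id="X", line_index=1, start_date=d, last_admin_date=d,
        agent_set=frozenset(agents), tmab_attached=tmab,
        tmab_agent="trastuzumab" if tmab else None, regimen_label=label,
    )


def test_tmab_group_over_any_line(catalog):
    xp_t = _line({"capecitabine", "cisplatin"}, "XP + T-mab", tmab=True)
    ptx = _line({"paclitaxel"}, "PTX")
    sox = _line({"s1", "oxaliplatin"}, "SOX")
    assert tmab_group([xp_t, ptx], catalog) == "tmab_pos"
    assert tmab_group([sox, ptx], catalog) == "tmab_neg"
    # antibody only in the third line still marks the patient
    assert tmab_group([sox, ptx, xp_t], catalog) == "tmab_pos"


def test_exclusion_reasons_partition_the_bundle(config, catalog):
    bundle, truth = simulate_cohort(SimulationParams(n_patients=300, seed=21), config, catalog)
    res = run_pipeline(bundle, catalog, config)

    flow = dict(exclusion_flow(res.adjuvant_cohort, ADJUVANT_RULE_ORDER))
    assert sum(flow.values()) == len(bundle.patients)
    # every excluded patient carries exactly one reason from the ordered list
    for rec in res.adjuvant_cohort:
        assert rec.included == (rec.exclusion_reason is None)
        if not rec.included:
            assert rec.exclusion_reason in ADJUVANT_RULE_ORDER

    rec_flow = dict(exclusion_flow(res.recurrent_cohort, RECURRENT_RULE_ORDER))
    assert sum(rec_flow.values()) == flow["included"]
    for rec in res.recurrent_cohort:
        if not rec.included:
            assert rec.exclusion_reason in RECURRENT_RULE_ORDER


def test_recurrent_cohort_nested_in_adjuvant_and_partitioned(config, catalog):
    bundle, _ = simulate_cohort(SimulationParams(n_patients=300, seed=22), config, catalog)
    res = run_pipeline(bundle, catalog, config)
    adj_ids = {r.patient_id for r in res.adjuvant_cohort if r.included}
    rec_members = [r for r in res.recurrent_cohort if r.included]
    assert {r.patient_id for r in rec_members} <= adj_ids
    # early/late and antibody-history groups partition the recurrent cohort
    assert all(r.recurrence_timing in ("early", "late") for r in rec_members)
    assert all(r.tmab_group in ("tmab_neg", "tmab_pos") for r in rec_members)


def test_early_cohort_nests_under_wider_threshold(config, catalog):
    bundle, _ = simulate_cohort(SimulationParams(n_patients=300, seed=23), config, catalog)
    res180 = run_pipeline(bundle, catalog, config)
    res210 = run_pipeline(bundle, catalog, config.replace(early_late_threshold_days=210))
    early = {
        t: {
            r.patient_id
            for r in res.recurrent_cohort
            if r.included and r.recurrence_timing == "early"
        }
        for t, res in ((180, res180), (210, res210))
    }
    assert early[180] <= early[210]
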