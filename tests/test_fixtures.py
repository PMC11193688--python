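"""Hand-traced fixtures: the pipeline must reproduce every documented truth."""

from __future__ import annotations

import pytest

from gclot import (
    FIXTURES,
    StudyConfig,
    make_fixture,
    run_pipeline,
    verify_against_truth,
)


@pytest.mark.parametrize("name", sorted(FIXTURES))
def test_fixture_truth_is_recovered(name, config, catalog):
    bundle, truth = make_fixture(name)
    result = run_pipeline(bundle, catalog, config)
    report = verify_against_truth(result, truth, bundle)
    assert report.all_match, report.mismatches


@pytest.mark.parametrize("name", sorted(FIXTURES))
def test_fixture_line_streams_segment_as_documented(name, config, catalog):
    """Standalone line fixtures record raw segmentation truth; check it."""
    bundle, truth = make_fixture(name)
    result = run_pipeline(bundle, catalog, config)
    for pid, t in truth.patients.items():
        if t.adjuvant_exclusion_reason == "no_gc_diagnosis" and t.lines:
            got = [
                (l.line_index, l.start_date, l.last_admin_date, l.regimen_label,
                 l.end_reason, l.event_observed)
                for l in result.lines_per_patient[pid]
            ]
            want = [
                (l.line_index, l.start, l.last_admin, l.regimen_label,
                 l.end_reason, l.event_observed)
                for l in t.lines
            ]
            assert got == want, (name, pid)


def test_gap_split_fixture_is_threshold_sensitive(catalog):
    """A 100-day silence: one line under the 120-day rule, two under 90."""
    bundle, _ = make_fixture("gap_split_100")
    base = run_pipeline(bundle, catalog, StudyConfig())
    tight = run_pipeline(bundle, catalog, StudyConfig(line_gap_days=90))
    (pid,) = bundle.patients
    assert len(base.lines_per_patient[pid]) == 1
    assert len(tight.lines_per_patient[pid]) == 2


def test_unknown_fixture_lists_available_cases():
    with pytest.raises(KeyError, match="clean_adjuvant"):
        make_fixture("definitely_not_a_case")


def test_fixture_library_covers_all_rule_families():
    names = set(FIXTURES)
    assert len(names) >= 15
    assert {n for n in names if n.startswith("excl_")}  # cohort exclusions
    assert {"gap_split_121", "gap_no_split_120", "combo_window_join",
            "new_agent_split"} <= names  # segmentation rules
    assert {"tmab_late_attach", "tmab_early_attach", "tmab_orphan"} <= names
    assert {"censored_line", "death_event"} <= names  # censoring rules
    assert "gap_split_100" in names  # sensitivity branch
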