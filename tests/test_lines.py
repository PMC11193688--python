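"""Line segmentation, HER2-antibody attachment, and duration rules."""

from __future__ import annotations

import numpy as np
import pytest
from _oracles import brute_force_segment
from conftest import BASE, day_of, patient, rx_stream

from gclot import StudyConfig, line_duration, overall_duration, segment_lines

AGENTS = ["s1", "paclitaxel", "oxaliplatin", "irinotecan"]


def segments(stream, catalog, config, pat=None):
    lines = segment_lines(rx_stream(stream), catalog, config, pat or patient())
    return [
        (day_of(l.start_date), day_of(l.last_admin_date), set(l.agent_set), l.regimen_label)
        for l in lines
    ]


def test_single_agent_cycles_form_one_line(catalog, config):
    got = segments([(0, "s1"), (21, "s1"), (42, "s1")], catalog, config)
    assert got == [(0, 42, {"s1"}, "S-1")]


def test_gap_beyond_threshold_splits_even_for_identical_agent(catalog, config):
    got = segments([(0, "s1"), (21, "s1"), (163, "s1")], catalog, config)
    assert [(g[0], g[1]) for g in got] == [(0, 21), (163, 163)]
    assert all(g[3] == "S-1" for g in got)


def test_gap_exactly_at_threshold_continues_the_line(catalog, config):
    got = segments([(0, "s1"), (120, "s1")], catalog, config)
    assert got == [(0, 120, {"s1"}, "S-1")]


def test_agent_joining_within_window_extends_combination(catalog, config):
    stream = [(d, "s1") for d in range(0, 85, 21)] + [(84, "oxaliplatin")]
    got = segments(stream, catalog, config)
    assert got == [(0, 84, {"s1", "oxaliplatin"}, "SOX")]


def test_new_agent_beyond_window_opens_next_line(catalog, config):
    stream = [(d, "s1") for d in range(0, 85, 21)]
    stream += [(100, "paclitaxel"), (100, "ramucirumab"), (114, "paclitaxel"), (114, "ramucirumab")]
    got = segments(stream, catalog, config)
    assert got[0] == (0, 84, {"s1"}, "S-1")
    assert got[1] == (100, 114, {"paclitaxel", "ramucirumab"}, "PTX + RAM")


def test_same_day_tie_member_stays_new_agent_opens(catalog, config):
    # S-1 on the very day paclitaxel arrives: the S-1 administration closes
    # out the old line, paclitaxel opens the next line on the same day
    stream = [(0, "s1"), (50, "s1"), (100, "s1"), (100, "paclitaxel")]
    got = segments(stream, catalog, config)
    assert got == [
        (0, 100, {"s1"}, "S-1"),
        (100, 100, {"paclitaxel"}, "PTX"),
    ]


def test_permutation_of_same_day_records_is_irrelevant(catalog, config):
    stream = [(0, "s1"), (50, "oxaliplatin"), (50, "s1"), (100, "paclitaxel")]
    base = segments(stream, catalog, config)
    assert segments(stream[::-1], catalog, config) == base


@pytest.mark.parametrize(
    "tmab_day,expected",
    [(30, "XP + T-mab"), (120, "XP + T-mab")],
    ids=["within_first_90_days", "after_first_90_days"],
)
def test_tmab_attaches_inside_line_span(catalog, config, tmab_day, expected):
    stream = [(d, "capecitabine") for d in range(0, 201, 20)]
    stream += [(d, "cisplatin") for d in range(0, 201, 20)]
    stream += [(tmab_day, "trastuzumab")]
    lines = segment_lines(rx_stream(stream), catalog, config, patient())
    assert len(lines) == 1
    assert lines[0].tmab_attached and lines[0].regimen_label == expected
    assert "trastuzumab" in lines[0].full_agent_set


def test_orphan_tmab_attaches_backward_within_gap_else_forward(catalog, config):
    xp = [(d, a) for d in range(0, 201, 20) for a in ("capecitabine", "cisplatin")]
    nxt = [(d, "paclitaxel") for d in (310, 324, 338)]
    # 100 days after line end: backward
    lines = segment_lines(
        rx_stream(xp + nxt + [(300, "trastuzumab")]), catalog, config, patient()
    )
    assert [l.regimen_label for l in lines] == ["XP + T-mab", "PTX"]
    # beyond the gap threshold: forward
    nxt2 = [(d, "paclitaxel") for d in (350, 364, 378)]
    lines = segment_lines(
        rx_stream(xp + nxt2 + [(340, "trastuzumab")]), catalog, config, patient()
    )
    assert [l.regimen_label for l in lines] == ["XP", "PTX + T-mab"]


def test_tmab_never_opens_or_ends_a_line(catalog, config):
    lines = segment_lines(
        rx_stream([(0, "trastuzumab"), (50, "s1"), (71, "s1")]), catalog, config, patient()
    )
    assert len(lines) == 1 and lines[0].agent_set == frozenset({"s1"})
    assert day_of(lines[0].start_date) == 50


# -- durations ---------------------------------------------------------------


def test_degenerate_single_administration_line(catalog, config):
    lines = segment_lines(rx_stream([(0, "s1")]), catalog, config, patient(last_day=300))
    days, event = line_duration(lines[0], patient(last_day=300), config)
    assert days == 0 and event  # 300-day silence: discontinued, not censored


def test_short_follow_up_censors_open_line(catalog, config):
    pat = patient(last_day=150)
    lines = segment_lines(
        rx_stream([(d, "s1") for d in range(0, 85, 21)]), catalog, config, pat
    )
    days, event = line_duration(lines[0], pat, config)
    assert days == 84 and not event  # 66-day gap to last record <= 120


def test_death_after_last_administration_is_an_event(catalog, config):
    pat = patient(last_day=110, death_day=100)
    lines = segment_lines(
        rx_stream([(d, "s1") for d in range(0, 85, 21)]), catalog, config, pat
    )
    days, event = line_duration(lines[0], pat, config)
    assert days == 84 and event
    assert lines[0].end_reason == "death"


def test_death_before_line_start_is_a_data_error(catalog, config):
    pat = patient(last_day=110, death_day=100)
    lines = segment_lines(
        rx_stream([(d, "s1") for d in range(0, 85, 21)]), catalog, config, pat
    )
    bad = patient(last_day=110, death_day=100)
    lines[0].start_date = bad.death_date.replace(year=bad.death_date.year + 1)
    lines[0].last_admin_date = lines[0].start_date
    with pytest.raises(ValueError, match="death"):
        line_duration(lines[0], bad, config)


def test_overall_duration_spans_first_to_last_line(catalog, config):
    pat = patient(last_day=600)
    stream = [(d, "s1") for d in range(0, 85, 21)]
    stream += [(d, "paclitaxel") for d in (100, 150, 200, 290)]
    lines = segment_lines(rx_stream(stream), catalog, config, pat)
    days, event = overall_duration(lines, pat, config)
    assert days == 290 and event
    # censoring inherited from the last line
    pat2 = patient(last_day=340)
    lines2 = segment_lines(rx_stream(stream), catalog, config, pat2)
    _, event2 = overall_duration(lines2, pat2, config)
    assert not event2


# -- properties ---------------------------------------------------------------


def _random_stream(rng):
    n = int(rng.integers(1, 13))
    k = int(rng.integers(1, 5))
    return sorted(
        {(int(rng.integers(0, 400)), AGENTS[int(rng.integers(0, k))]) for _ in range(n)}
    )


def test_brute_force_oracle_equivalence_on_random_streams(catalog, config):
    rng = np.random.default_rng(2024)
    for _ in range(300):
        stream = _random_stream(rng)
        sols = brute_force_segment(stream)
        assert len(sols) == 1, f"non-unique segmentation for {stream}"
        lines = segment_lines(rx_stream(stream), catalog, config, patient())
        got = [
            (day_of(l.start_date), day_of(l.last_admin_date), frozenset(l.agent_set))
            for l in lines
        ]
        assert got == sols[0], f"stream {stream}"


def test_every_administration_belongs_to_exactly_one_line(catalog, config):
    rng = np.random.default_rng(7)
    for _ in range(200):
        stream = _random_stream(rng)
        lines = segment_lines(rx_stream(stream), catalog, config, patient())
        covered = []
        for l in lines:
            covered.extend(
                (d, a)
                for d, a in stream
                if day_of(l.start_date) <= d <= day_of(l.last_admin_date)
                and a in l.agent_set
            )
        # each admin covered at least once and spans don't double-claim
        assert set(covered) == set(stream)
        for (s1_, e1, _), (s2, _, _) in zip(
            [(day_of(l.start_date), day_of(l.last_admin_date), None) for l in lines],
            [(day_of(l.start_date), None, None) for l in lines[1:]],
        ):
            assert e1 <= s2


def test_line_count_is_monotone_in_gap_threshold_on_simulated_streams(catalog, config):
    # margin-safe simulated prescription histories: widening the end-of-line
    # gap can only merge lines, never create them
    from gclot import SimulationParams, simulate_cohort

    bundle, _ = simulate_cohort(SimulationParams(n_patients=150, seed=5), config, catalog)
    gaps = [60, 90, 120, 180]
    checked = 0
    for pid, pat, rx, _, _ in bundle.grouped():
        if not rx:
            continue
        counts = [
            len(segment_lines(rx, catalog, StudyConfig(line_gap_days=g), pat))
            for g in gaps
        ]
        assert counts == sorted(counts, reverse=True), (pid, counts)
        checked += 1
    assert checked >= 100
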