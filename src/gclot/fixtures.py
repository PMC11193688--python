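"""Hand-built single-rule fixtures with hand-traced ground truth.

Each fixture is a tiny (1–2 patient) claims bundle exercising exactly one
cohort rule, line-segmentation rule, or sensitivity branch, with its
expected outcome written down next to the events.  Cohort fixtures are
fully consistent patients (diagnosis → resection → adjuvant → ...), so the
whole pipeline can be validated against the fixture truth; pure
line-segmentation fixtures are standalone prescription streams (no
gastric-cancer diagnosis) whose truth ``lines`` use the raw segmentation
numbering (1-based).
"""

from __future__ import annotations

from datetime import date, timedelta

from .records import (
    ClaimsBundle,
    DiagnosisRecord,
    PatientRecord,
    PrescriptionRecord,
    ProcedureRecord,
)
from .simulate import GroundTruth, TruthLine, TruthPatient

_D = timedelta


class _B:
    """Tiny accumulator for one fixture bundle."""

    def __init__(self):
        self.patients: dict[str, PatientRecord] = {}
        self.rx: list[PrescriptionRecord] = []
        self.dx: list[DiagnosisRecord] = []
        self.px: list[ProcedureRecord] = []
        self.truth: dict[str, TruthPatient] = {}

    def patient(self, pid, last_record, birth=(1947, 1), death=None):
        self.patients[pid] = PatientRecord(
            patient_id=pid,
            sex="male",
            birth_year_month=birth,
            death_date=death,
            last_record_date=last_record,
            hospital_is_designated_cancer=True,
            hospital_departments=frozenset({"surgery"}),
            hospital_bed_band="200-<500",
            adl_items=("independent",) * 10,
        )

    def give(self, pid, agents, dates):
        for d in dates:
            for a in agents:
                self.rx.append(PrescriptionRecord(pid, d, a))

    def gc(self, pid, when):
        self.dx.append(DiagnosisRecord(pid, when, "GC", "gastric_cancer"))

    def rec(self, pid, when):
        self.dx.append(DiagnosisRecord(pid, when, "REC", "recurrence"))

    def resect(self, pid, when):
        self.px.append(ProcedureRecord(pid, when, "GC_RESECTION", True, False))

    def trial(self, pid, when):
        self.px.append(ProcedureRecord(pid, when, "TRIAL_ENTRY", False, True))

    def done(self):
        bundle = ClaimsBundle(self.patients, self.rx, self.dx, self.px)
        return bundle, GroundTruth(self.truth)


def _truth(pid, **kw):
    base = dict(
        patient_id=pid,
        in_adjuvant=False,
        adjuvant_exclusion_reason=None,
        adjuvant_regimen=None,
        era=None,
        in_recurrent=False,
        recurrent_exclusion_reason=None,
        recurrence_date=None,
        recurrence_timing=None,
        tmab_group=None,
        lines=[],
    )
    base.update(kw)
    return TruthPatient(**base)


def _cycles(start: date, step: int, count: int) -> list[date]:
    return [start + _D(days=step * i) for i in range(count)]


# -- standard adjuvant skeleton ----------------------------------------------
# diagnosis day 0, resection day 30, S-1 from day 80 (resection + 50),
# 8 administrations every 21 days (span 147 days)


def _std_adjuvant(b: _B, pid: str, dx_day: date, follow_up_days=200, **pt_kw):
    resect = dx_day + _D(days=30)
    adj_start = resect + _D(days=50)
    dates = _cycles(adj_start, 21, 8)
    adj_end = dates[-1]
    b.patient(pid, adj_end + _D(days=follow_up_days), **pt_kw)
    b.gc(pid, dx_day)
    b.resect(pid, resect)
    b.give(pid, ["s1"], dates)
    return resect, adj_start, adj_end


# -- fixture builders ---------------------------------------------------------


def _clean_adjuvant():
    b = _B()
    dx = date(2017, 1, 1)
    _, adj_start, adj_end = _std_adjuvant(b, "F01", dx)
    # included: resection +30 <= 60; adjuvant +50 <= 90; age 70; era 2
    b.truth["F01"] = _truth(
        "F01",
        in_adjuvant=True,
        adjuvant_regimen="S-1",
        era=2,
        recurrent_exclusion_reason="no_recurrence_after_adjuvant",
        lines=[TruthLine(0, adj_start, adj_end, "S-1", "gap_elapsed", True)],
    )
    return b.done()


def _excl_no_gc_diagnosis():
    b = _B()
    resect = date(2017, 1, 31)
    adj_start = resect + _D(days=50)
    dates = _cycles(adj_start, 21, 8)
    b.patient("F02", dates[-1] + _D(days=200))
    b.resect("F02", resect)
    b.give("F02", ["s1"], dates)
    b.truth["F02"] = _truth("F02", adjuvant_exclusion_reason="no_gc_diagnosis")
    return b.done()


def _excl_no_resection_within_60d():
    b = _B()
    dx = date(2017, 1, 1)
    resect = dx + _D(days=70)  # > 60 days after diagnosis
    adj_start = resect + _D(days=50)
    dates = _cycles(adj_start, 21, 8)
    b.patient("F03", dates[-1] + _D(days=200))
    b.gc("F03", dx)
    b.resect("F03", resect)
    b.give("F03", ["s1"], dates)
    b.truth["F03"] = _truth("F03", adjuvant_exclusion_reason="no_resection_within_60d")
    return b.done()


def _excl_no_adjuvant_within_90d():
    b = _B()
    dx = date(2017, 1, 1)
    resect = dx + _D(days=30)
    adj_start = resect + _D(days=100)  # > 90 days after resection
    dates = _cycles(adj_start, 21, 8)
    b.patient("F04", dates[-1] + _D(days=200))
    b.gc("F04", dx)
    b.resect("F04", resect)
    b.give("F04", ["s1"], dates)
    b.truth["F04"] = _truth("F04", adjuvant_exclusion_reason="no_adjuvant_within_90d")
    return b.done()


def _excl_non_adjuvant_agent_post_surgery():
    b = _B()
    dx = date(2017, 1, 1)
    _, adj_start, _ = _std_adjuvant(b, "F05", dx)
    # irinotecan joins the adjuvant line 30 days in: concomitant non-adjuvant agent
    b.give("F05", ["irinotecan"], [adj_start + _D(days=30)])
    b.truth["F05"] = _truth(
        "F05", adjuvant_exclusion_reason="non_adjuvant_agent_post_surgery"
    )
    return b.done()


def _excl_recurrence_before_adjuvant_end():
    b = _B()
    dx = date(2017, 1, 1)
    _, adj_start, _ = _std_adjuvant(b, "F06", dx)
    b.rec("F06", adj_start + _D(days=70))  # during adjuvant therapy
    b.truth["F06"] = _truth(
        "F06", adjuvant_exclusion_reason="recurrence_before_adjuvant_end"
    )
    return b.done()


def _excl_presurgery_agent():
    b = _B()
    dx = date(2017, 1, 1)
    resect = dx + _D(days=30)
    adj_start = resect + _D(days=80)
    dates = _cycles(adj_start, 21, 5)
    b.patient("F07", dates[-1] + _D(days=200))
    b.gc("F07", dx)
    b.resect("F07", resect)
    b.give("F07", ["s1"], [resect - _D(days=10)])  # S-1 ten days before resection
    b.give("F07", ["s1"], dates)
    b.truth["F07"] = _truth(
        "F07", adjuvant_exclusion_reason="pre_surgery_antitumor_agent"
    )
    return b.done()


def _excl_underage():
    b = _B()
    dx = date(2017, 1, 1)
    _std_adjuvant(b, "F08", dx, birth=(1998, 1))  # age 19 at adjuvant start
    b.truth["F08"] = _truth("F08", adjuvant_exclusion_reason="age")
    return b.done()


def _excl_before_enrollment():
    b = _B()
    dx = date(2008, 6, 1)
    resect = dx + _D(days=30)
    adj_start = resect + _D(days=62)  # 2008-09-01, before enrollment opens
    dates = _cycles(adj_start, 21, 8)
    b.patient("F09", dates[-1] + _D(days=200))
    b.gc("F09", dx)
    b.resect("F09", resect)
    b.give("F09", ["s1"], dates)
    assert adj_start == date(2008, 9, 1)
    b.truth["F09"] = _truth("F09", adjuvant_exclusion_reason="before_enrollment_start")
    return b.done()


def _excl_trial_participation():
    b = _B()
    dx = date(2017, 1, 1)
    resect, _, _ = _std_adjuvant(b, "F10", dx)
    b.trial("F10", resect + _D(days=40))
    b.truth["F10"] = _truth("F10", adjuvant_exclusion_reason="trial_participation")
    return b.done()


def _recurrent_early():
    # adjuvant span 100 days; recurrence +30 after adjuvant end; 1L PTX+RAM
    # +40 days -> included, early (40 <= 180); prior line ends by new agent
    b = _B()
    dx = date(2017, 1, 1)
    resect = dx + _D(days=30)
    adj_start = resect + _D(days=50)
    adj_dates = _cycles(adj_start, 20, 6)  # span 100
    adj_end = adj_dates[-1]
    l1_start = adj_end + _D(days=40)
    l1_dates = _cycles(l1_start, 14, 7)  # span 84
    b.patient("F11", l1_dates[-1] + _D(days=200))
    b.gc("F11", dx)
    b.resect("F11", resect)
    b.give("F11", ["s1"], adj_dates)
    b.rec("F11", adj_end + _D(days=30))
    b.give("F11", ["paclitaxel", "ramucirumab"], l1_dates)
    b.truth["F11"] = _truth(
        "F11",
        in_adjuvant=True,
        adjuvant_regimen="S-1",
        era=2,
        in_recurrent=True,
        recurrence_date=adj_end + _D(days=30),
        recurrence_timing="early",
        tmab_group="tmab_neg",
        lines=[
            TruthLine(0, adj_start, adj_end, "S-1", "new_agent", True),
            TruthLine(1, l1_start, l1_dates[-1], "PTX + RAM", "gap_elapsed", True),
        ],
    )
    return b.done()


def _recurrent_late():
    # 1L SOX starting 200 days after adjuvant end -> late recurrence
    b = _B()
    dx = date(2016, 1, 1)
    resect = dx + _D(days=30)
    adj_start = resect + _D(days=50)
    adj_dates = _cycles(adj_start, 21, 8)
    adj_end = adj_dates[-1]
    l1_start = adj_end + _D(days=200)
    l1_dates = _cycles(l1_start, 14, 7)
    b.patient("F12", l1_dates[-1] + _D(days=60))  # censored final line
    b.gc("F12", dx)
    b.resect("F12", resect)
    b.give("F12", ["s1"], adj_dates)
    b.rec("F12", adj_end + _D(days=150))
    b.give("F12", ["s1", "oxaliplatin"], l1_dates)
    b.truth["F12"] = _truth(
        "F12",
        in_adjuvant=True,
        adjuvant_regimen="S-1",
        era=1,
        in_recurrent=True,
        recurrence_date=adj_end + _D(days=150),
        recurrence_timing="late",
        tmab_group="tmab_neg",
        lines=[
            TruthLine(0, adj_start, adj_end, "S-1", "gap_elapsed", True),
            TruthLine(1, l1_start, l1_dates[-1], "SOX", "censored", False),
        ],
    )
    return b.done()


def _excl_short_adjuvant():
    # 20-day adjuvant prescription span -> excluded from the recurrent cohort
    b = _B()
    dx = date(2017, 1, 1)
    resect = dx + _D(days=30)
    adj_start = resect + _D(days=50)
    adj_dates = [adj_start, adj_start + _D(days=20)]
    adj_end = adj_dates[-1]
    l1_start = adj_end + _D(days=140)  # gap split keeps lines separate
    l1_dates = _cycles(l1_start, 14, 5)
    b.patient("F13", l1_dates[-1] + _D(days=200))
    b.gc("F13", dx)
    b.resect("F13", resect)
    b.give("F13", ["s1"], adj_dates)
    b.rec("F13", adj_end + _D(days=30))
    b.give("F13", ["paclitaxel", "ramucirumab"], l1_dates)
    b.truth["F13"] = _truth(
        "F13",
        in_adjuvant=True,
        adjuvant_regimen="S-1",
        era=2,
        recurrent_exclusion_reason="short_adjuvant",
        lines=[TruthLine(0, adj_start, adj_end, "S-1", "gap_elapsed", True)],
    )
    return b.done()


def _excl_1l_outside_window():
    # post-recurrent 1L starting 2022-01-15, outside the enrollment window
    b = _B()
    dx = date(2021, 1, 2)
    resect = dx + _D(days=30)
    adj_start = resect + _D(days=50)  # 2021-03-23
    adj_dates = _cycles(adj_start, 20, 6)  # span 100, end 2021-07-01
    adj_end = adj_dates[-1]
    l1_start = date(2022, 1, 15)
    l1_dates = _cycles(l1_start, 14, 5)  # last 2022-03-12
    b.patient("F14", date(2022, 3, 31))
    b.gc("F14", dx)
    b.resect("F14", resect)
    b.give("F14", ["s1"], adj_dates)
    b.rec("F14", adj_end + _D(days=60))
    b.give("F14", ["paclitaxel", "ramucirumab"], l1_dates)
    b.truth["F14"] = _truth(
        "F14",
        in_adjuvant=True,
        adjuvant_regimen="S-1",
        era=3,
        recurrent_exclusion_reason="first_line_outside_window",
        lines=[TruthLine(0, adj_start, adj_end, "S-1", "gap_elapsed", True)],
    )
    return b.done()


def _excl_no_qualifying_first_line():
    # first post-recurrent line is an off-catalog combination
    b = _B()
    dx = date(2017, 1, 1)
    resect = dx + _D(days=30)
    adj_start = resect + _D(days=50)
    adj_dates = _cycles(adj_start, 21, 8)
    adj_end = adj_dates[-1]
    l1_start = adj_end + _D(days=140)
    l1_dates = _cycles(l1_start, 14, 5)
    b.patient("F15", l1_dates[-1] + _D(days=200))
    b.gc("F15", dx)
    b.resect("F15", resect)
    b.give("F15", ["s1"], adj_dates)
    b.rec("F15", adj_end + _D(days=30))
    b.give("F15", ["capecitabine", "irinotecan"], l1_dates)
    b.truth["F15"] = _truth(
        "F15",
        in_adjuvant=True,
        adjuvant_regimen="S-1",
        era=2,
        recurrent_exclusion_reason="no_qualifying_first_line",
        lines=[TruthLine(0, adj_start, adj_end, "S-1", "gap_elapsed", True)],
    )
    return b.done()


# -- standalone line-segmentation fixtures (1-based raw line numbering) -------


def _gap_split_121():
    b = _B()
    d0 = date(2018, 1, 1)
    dates = [d0, d0 + _D(days=21), d0 + _D(days=21 + 121)]
    b.patient("F16", dates[-1] + _D(days=200))
    b.give("F16", ["s1"], dates)
    b.truth["F16"] = _truth(
        "F16",
        adjuvant_exclusion_reason="no_gc_diagnosis",
        lines=[
            TruthLine(1, d0, d0 + _D(days=21), "S-1", "gap_elapsed", True),
            TruthLine(2, dates[-1], dates[-1], "S-1", "gap_elapsed", True),
        ],
    )
    return b.done()


def _gap_no_split_120():
    b = _B()
    d0 = date(2018, 1, 1)
    dates = [d0, d0 + _D(days=120), d0 + _D(days=140)]
    b.patient("F17", dates[-1] + _D(days=200))
    b.give("F17", ["s1"], dates)
    b.truth["F17"] = _truth(
        "F17",
        adjuvant_exclusion_reason="no_gc_diagnosis",
        lines=[TruthLine(1, d0, dates[-1], "S-1", "gap_elapsed", True)],
    )
    return b.done()


def _combo_window_join():
    b = _B()
    d0 = date(2018, 1, 1)
    s1_dates = _cycles(d0, 21, 5)  # days 0..84
    b.patient("F18", s1_dates[-1] + _D(days=200))
    b.give("F18", ["s1"], s1_dates)
    b.give("F18", ["oxaliplatin"], [d0 + _D(days=84)])  # joins: 84 <= 90
    b.truth["F18"] = _truth(
        "F18",
        adjuvant_exclusion_reason="no_gc_diagnosis",
        lines=[TruthLine(1, d0, s1_dates[-1], "SOX", "gap_elapsed", True)],
    )
    # second patient: oxaliplatin on day 91 arrives beyond the window
    d1 = date(2018, 1, 1)
    s1b = _cycles(d1, 21, 5)
    ox_day = d1 + _D(days=91)
    b.patient("F18b", ox_day + _D(days=200))
    b.give("F18b", ["s1"], s1b)
    b.give("F18b", ["oxaliplatin"], [ox_day])
    b.truth["F18b"] = _truth(
        "F18b",
        adjuvant_exclusion_reason="no_gc_diagnosis",
        lines=[
            TruthLine(1, d1, s1b[-1], "S-1", "new_agent", True),
            TruthLine(2, ox_day, ox_day, "OX", "gap_elapsed", True),
        ],
    )
    return b.done()


def _new_agent_split():
    b = _B()
    d0 = date(2018, 1, 1)
    s1_dates = _cycles(d0, 21, 5)  # days 0..84
    l2_dates = _cycles(d0 + _D(days=100), 14, 5)
    b.patient("F19", l2_dates[-1] + _D(days=200))
    b.give("F19", ["s1"], s1_dates)
    b.give("F19", ["paclitaxel", "ramucirumab"], l2_dates)
    b.truth["F19"] = _truth(
        "F19",
        adjuvant_exclusion_reason="no_gc_diagnosis",
        lines=[
            TruthLine(1, d0, s1_dates[-1], "S-1", "new_agent", True),
            TruthLine(2, l2_dates[0], l2_dates[-1], "PTX + RAM", "gap_elapsed", True),
        ],
    )
    return b.done()


def _tmab_late_attach():
    b = _B()
    d0 = date(2018, 1, 1)
    xp = _cycles(d0, 20, 11)  # days 0..200
    b.patient("F20", xp[-1] + _D(days=200))
    b.give("F20", ["capecitabine", "cisplatin"], xp)
    b.give("F20", ["trastuzumab"], [d0 + _D(days=120)])  # after the first 90 days
    b.truth["F20"] = _truth(
        "F20",
        adjuvant_exclusion_reason="no_gc_diagnosis",
        lines=[TruthLine(1, d0, xp[-1], "XP + T-mab", "gap_elapsed", True)],
    )
    return b.done()


def _tmab_early_attach():
    b = _B()
    d0 = date(2018, 1, 1)
    xp = _cycles(d0, 20, 11)
    b.patient("F21", xp[-1] + _D(days=200))
    b.give("F21", ["capecitabine", "cisplatin"], xp)
    b.give("F21", ["trastuzumab"], [d0 + _D(days=30)])  # within the first 90 days
    b.truth["F21"] = _truth(
        "F21",
        adjuvant_exclusion_reason="no_gc_diagnosis",
        lines=[TruthLine(1, d0, xp[-1], "XP + T-mab", "gap_elapsed", True)],
    )
    return b.done()


def _tmab_orphan():
    b = _B()
    d0 = date(2018, 1, 1)
    xp = _cycles(d0, 20, 11)  # line 1 ends day 200
    # backward: orphan 100 days after line end (<= 120) attaches to line 1
    l2 = _cycles(d0 + _D(days=310), 14, 5)
    b.patient("F22", l2[-1] + _D(days=200))
    b.give("F22", ["capecitabine", "cisplatin"], xp)
    b.give("F22", ["trastuzumab"], [d0 + _D(days=300)])
    b.give("F22", ["paclitaxel"], l2)
    b.truth["F22"] = _truth(
        "F22",
        adjuvant_exclusion_reason="no_gc_diagnosis",
        lines=[
            TruthLine(1, d0, xp[-1], "XP + T-mab", "new_agent", True),
            TruthLine(2, l2[0], l2[-1], "PTX", "gap_elapsed", True),
        ],
    )
    # forward: orphan 140 days after line end (> 120) attaches to next line
    l2b = _cycles(d0 + _D(days=350), 14, 5)
    b.patient("F22b", l2b[-1] + _D(days=200))
    b.give("F22b", ["capecitabine", "cisplatin"], xp)
    b.give("F22b", ["trastuzumab"], [d0 + _D(days=340)])
    b.give("F22b", ["paclitaxel"], l2b)
    b.truth["F22b"] = _truth(
        "F22b",
        adjuvant_exclusion_reason="no_gc_diagnosis",
        lines=[
            TruthLine(1, d0, xp[-1], "XP", "gap_elapsed", True),
            TruthLine(2, l2b[0], l2b[-1], "PTX + T-mab", "gap_elapsed", True),
        ],
    )
    return b.done()


def _censored_line():
    # 66 days between last administration and last record: possibly ongoing
    b = _B()
    d0 = date(2018, 1, 1)
    dates = _cycles(d0, 21, 5)  # last admin day 84
    b.patient("F23", d0 + _D(days=150))
    b.give("F23", ["s1"], dates)
    b.truth["F23"] = _truth(
        "F23",
        adjuvant_exclusion_reason="no_gc_diagnosis",
        lines=[TruthLine(1, d0, dates[-1], "S-1", "censored", False)],
    )
    return b.done()


def _death_event():
    b = _B()
    d0 = date(2018, 1, 1)
    dates = _cycles(d0, 21, 5)
    b.patient("F24", d0 + _D(days=110), death=d0 + _D(days=100))
    b.give("F24", ["s1"], dates)
    b.truth["F24"] = _truth(
        "F24",
        adjuvant_exclusion_reason="no_gc_diagnosis",
        lines=[TruthLine(1, d0, dates[-1], "S-1", "death", True)],
    )
    return b.done()


def _gap_split_100():
    # 100-day gap: one line under the 120-day rule, two under the 90-day rule
    b = _B()
    d0 = date(2018, 1, 1)
    dates = [d0, d0 + _D(days=21), d0 + _D(days=121), d0 + _D(days=142)]
    b.patient("F25", dates[-1] + _D(days=200))
    b.give("F25", ["s1"], dates)
    b.truth["F25"] = _truth(
        "F25",
        adjuvant_exclusion_reason="no_gc_diagnosis",
        lines=[TruthLine(1, d0, dates[-1], "S-1", "gap_elapsed", True)],
    )
    return b.done()


FIXTURES = {
    "clean_adjuvant": _clean_adjuvant,
    "excl_no_gc_diagnosis": _excl_no_gc_diagnosis,
    "excl_no_resection_within_60d": _excl_no_resection_within_60d,
    "excl_no_adjuvant_within_90d": _excl_no_adjuvant_within_90d,
    "excl_non_adjuvant_agent_post_surgery": _excl_non_adjuvant_agent_post_surgery,
    "excl_recurrence_before_adjuvant_end": _excl_recurrence_before_adjuvant_end,
    "excl_presurgery_agent": _excl_presurgery_agent,
    "excl_underage": _excl_underage,
    "excl_before_enrollment": _excl_before_enrollment,
    "excl_trial_participation": _excl_trial_participation,
    "recurrent_early": _recurrent_early,
    "recurrent_late": _recurrent_late,
    "excl_short_adjuvant": _excl_short_adjuvant,
    "excl_1l_outside_window": _excl_1l_outside_window,
    "excl_no_qualifying_first_line": _excl_no_qualifying_first_line,
    "gap_split_121": _gap_split_121,
    "gap_no_split_120": _gap_no_split_120,
    "combo_window_join": _combo_window_join,
    "new_agent_split": _new_agent_split,
    "tmab_late_attach": _tmab_late_attach,
    "tmab_early_attach": _tmab_early_attach,
    "tmab_orphan": _tmab_orphan,
    "censored_line": _censored_line,
    "death_event": _death_event,
    "gap_split_100": _gap_split_100,
}


def make_fixture(case_name: str) -> tuple[ClaimsBundle, GroundTruth]:
    """Build the named fixture; unknown names raise with the full menu."""
    try:
        builder = FIXTURES[case_name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {case_name!r}; available: {', '.join(sorted(FIXTURES))}"
        ) from None
    return builder()
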