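"""Line-of-therapy segmentation from a dated prescription stream.

The segmenter walks a patient's antitumor administrations once, left to
right, applying the claims conventions used for gastric-cancer treatment
pattern studies:

1. a line opens at the first unconsumed non-HER2-antibody administration;
2. an agent joins the line's combination iff its first administration falls
   within ``combination_window_days`` (default 90) of the line start;
3. an administration of a non-member agent later than the combination
   window ends the current line (``new_agent``) and opens the next line on
   that date;
4. a gap longer than ``line_gap_days`` (default 120) between member
   administrations ends the line (``gap_elapsed``) — even for identical
   agents;
5. trastuzumab / trastuzumab deruxtecan administrations never open or end
   a line; they are attached afterwards (:func:`attach_tmab`).

All day comparisons are inclusive ("within N days" = ``0 <= diff <= N``).
Same-day ties between a member administration and a new agent are resolved
deterministically: the member administration closes out the old line, the
new agent opens the next line on the same day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

from .catalog import RegimenCatalog, classify_regimen
from .config import StudyConfig
from .records import PatientRecord, PrescriptionRecord

END_REASONS = ("gap_elapsed", "new_agent", "death", "censored")


@dataclass
class TreatmentLine:
    patient_id: str
    line_index: int  # 0 = adjuvant, 1.. = post-recurrent; set by callers
    start_date: date
    last_admin_date: date
    agent_set: frozenset[str]
    tmab_attached: bool = False
    tmab_agent: str | None = None  # agent code of the attached HER2 antibody
    regimen_label: str = ""
    end_reason: str = "censored"
    event_observed: bool = True
    admin_dates: tuple[date, ...] = field(default_factory=tuple)

    @property
    def full_agent_set(self) -> frozenset[str]:
        if self.tmab_attached and self.tmab_agent:
            return self.agent_set | {self.tmab_agent}
        return self.agent_set

    def duration_days(self) -> int:
        return (self.last_admin_date - self.start_date).days


def segment_lines(
    prescriptions: list[PrescriptionRecord],
    catalog: RegimenCatalog,
    config: StudyConfig,
    patient: PatientRecord,
) -> list[TreatmentLine]:
    """Segment one patient's administrations into ordered treatment lines.

    HER2-antibody administrations are excluded from segmentation and then
    attached via :func:`attach_tmab`.  The final line's ``end_reason`` and
    ``event_observed`` are resolved against the patient's death and last
    record dates (death always yields an observed event; otherwise a
    follow-up gap of at most ``line_gap_days`` after the last administration
    censors the line).
    """
    admins = sorted(prescriptions, key=lambda r: (r.date, r.agent_code))
    for a in admins:
        if a.date > patient.last_record_date:
            raise ValueError(
                f"{patient.patient_id}: administration {a.agent_code} on {a.date} "
                f"after last_record_date {patient.last_record_date}"
            )
    tmab = [a for a in admins if catalog.is_tmab(a.agent_code)]
    base = [a for a in admins if not catalog.is_tmab(a.agent_code)]

    lines: list[TreatmentLine] = []
    cur_agents: set[str] = set()
    cur_start: date | None = None
    cur_last: date | None = None
    cur_dates: list[date] = []

    def close(reason: str) -> None:
        assert cur_start is not None and cur_last is not None
        lines.append(
            TreatmentLine(
                patient_id=patient.patient_id,
                line_index=len(lines) + 1,
                start_date=cur_start,
                last_admin_date=cur_last,
                agent_set=frozenset(cur_agents),
                regimen_label=classify_regimen(cur_agents, catalog),
                end_reason=reason,
                admin_dates=tuple(cur_dates),
            )
        )

    i = 0
    n = len(base)
    while i < n:
        day = base[i].date
        group = []
        while i < n and base[i].date == day:
            group.append(base[i].agent_code)
            i += 1
        group_set = set(group)

        if cur_start is None:
            cur_start, cur_last = day, day
            cur_agents = group_set
            cur_dates = [day]
            continue

        gap = (day - cur_last).days
        if gap > config.line_gap_days:
            close("gap_elapsed")
            cur_start, cur_last = day, day
            cur_agents = set(group_set)
            cur_dates = [day]
            continue

        members = group_set & cur_agents
        newcomers = group_set - cur_agents
        # member administrations always belong to the open line (same-day
        # tie rule: the member admin is consumed before any new agent acts)
        if members:
            cur_last = day
            cur_dates.append(day)
        within_window = (day - cur_start).days <= config.combination_window_days
        if newcomers:
            if within_window:
                cur_agents |= newcomers
                cur_last = day
                if not members:
                    cur_dates.append(day)
                elif day != cur_dates[-1]:
                    cur_dates.append(day)
            else:
                close("new_agent")
                cur_start, cur_last = day, day
                cur_agents = set(newcomers)
                cur_dates = [day]

    if cur_start is not None:
        # final line: resolve end reason against death / end of follow-up
        if patient.death_date is not None:
            close("death")
        elif (patient.last_record_date - cur_last).days <= config.line_gap_days:
            close("censored")
        else:
            close("gap_elapsed")

    attach_tmab(lines, tmab, catalog, config)
    for line in lines:
        _, line.event_observed = line_duration(line, patient, config)
    return lines


def attach_tmab(
    lines: list[TreatmentLine],
    tmab_administrations: list[PrescriptionRecord],
    catalog: RegimenCatalog,
    config: StudyConfig,
) -> list[TreatmentLine]:
    """Attach HER2-antibody administrations to segmented lines.

    An administration dated inside a line's [start, last administration]
    span marks that line.  Orphan administrations (in no span) attach to the
    preceding line when they fall within ``line_gap_days`` of its last
    administration, else to the following line; this mirrors the
    continuation semantics of the gap rule.
    """
    if not tmab_administrations:
        return lines
    for adm in sorted(tmab_administrations, key=lambda r: (r.date, r.agent_code)):
        target: TreatmentLine | None = None
        for line in lines:
            if line.start_date <= adm.date <= line.last_admin_date:
                target = line
                break
        if target is None:
            prev = [l for l in lines if l.last_admin_date < adm.date]
            nxt = [l for l in lines if l.start_date > adm.date]
            if prev and (adm.date - prev[-1].last_admin_date).days <= config.line_gap_days:
                target = prev[-1]
            elif nxt:
                target = nxt[0]
            elif prev:
                target = prev[-1]
        if target is not None and not target.tmab_attached:
            target.tmab_attached = True
            target.tmab_agent = adm.agent_code
            target.regimen_label = (
                f"{target.regimen_label} + {catalog.display(adm.agent_code)}"
            )
    return lines


def line_duration(
    line: TreatmentLine, patient: PatientRecord, config: StudyConfig
) -> tuple[int, bool]:
    """Duration in days and event indicator for one line.

    Time runs from the first to the last administration of the line.  The
    line is censored (event False) only when treatment may be ongoing at the
    end of follow-up: no death on record, the line was not ended by a new
    agent, and at most ``line_gap_days`` separate the last administration
    from the patient's last record.
    """
    if patient.death_date is not None and patient.death_date < line.start_date:
        raise ValueError(
            f"{patient.patient_id}: death {patient.death_date} precedes line start "
            f"{line.start_date}"
        )
    time_days = line.duration_days()
    censored = (
        patient.death_date is None
        and line.end_reason != "new_agent"
        and (patient.last_record_date - line.last_admin_date).days <= config.line_gap_days
    )
    return time_days, not censored


def overall_duration(
    post_recurrent_lines: list[TreatmentLine],
    patient: PatientRecord,
    config: StudyConfig,
) -> tuple[int, bool]:
    """Overall treatment duration: first administration of post-recurrent
    first-line therapy to last administration of the last line; censoring is
    inherited from the last line."""
    if not post_recurrent_lines:
        raise ValueError("at least one post-recurrent line required")
    ordered = sorted(post_recurrent_lines, key=lambda l: l.start_date)
    time_days = (ordered[-1].last_admin_date - ordered[0].start_date).days
    _, event = line_duration(ordered[-1], patient, config)
    return time_days, event
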