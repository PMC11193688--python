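"""Segment a hand-written prescription stream into treatment lines.

The stream below is a classic post-recurrent course: S-1 monotherapy,
then paclitaxel + ramucirumab starting 100 days after the S-1 line began
(beyond the 90-day combination window, so it opens a new line), with
trastuzumab added mid-line (attaching to the line it falls inside).
"""

from datetime import date, timedelta

from gclot import StudyConfig, default_catalog, segment_lines
from gclot.records import PatientRecord, PrescriptionRecord

base = date(2018, 1, 1)
patient = PatientRecord(
    patient_id="EX", sex="male", birth_year_month=(1950, 1), death_date=None,
    last_record_date=base + timedelta(days=600),
    hospital_is_designated_cancer=True,
    hospital_departments=frozenset({"surgery"}), hospital_bed_band="200-<500",
    adl_items=("independent",) * 10,
)

stream = [(d, "s1") for d in (0, 21, 42, 63, 84)]
stream += [(d, "paclitaxel") for d in (100, 114, 128, 142)]
stream += [(d, "ramucirumab") for d in (100, 114, 128, 142)]
stream += [(130, "trastuzumab")]
rx = [PrescriptionRecord("EX", base + timedelta(days=d), a) for d, a in stream]

lines = segment_lines(rx, default_catalog(), StudyConfig(), patient)
for line in lines:
    print(
        f"line {line.line_index}: {line.regimen_label:<16} "
        f"day {(line.start_date - base).days:>3} -> {(line.last_admin_date - base).days:>3}  "
        f"end={line.end_reason} event={line.event_observed}"
    )
# Expected: line 1 "S-1" (days 0-84, closed by the new agent), line 2
# "PTX + RAM + T-mab" (days 100-142, censoring resolved against follow-up).
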