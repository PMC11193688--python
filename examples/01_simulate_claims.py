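"""Generate a synthetic gastric-cancer claims bundle with known truth.

Builds a 50-patient cohort (diagnosis → resection → adjuvant cycles →
optional recurrence → palliative lines) and prints one patient's event
timeline.  The ground truth records what the pipeline must recover.
"""

from gclot import SimulationParams, StudyConfig, default_catalog, simulate_cohort

params = SimulationParams(n_patients=50, seed=42)
bundle, truth = simulate_cohort(params, StudyConfig(), default_catalog())

n_adj = sum(t.in_adjuvant for t in truth.patients.values())
n_rec = sum(t.in_recurrent for t in truth.patients.values())
print(f"patients:        {len(bundle.patients)}")
print(f"prescriptions:   {len(bundle.prescriptions)}")
print(f"diagnoses:       {len(bundle.diagnoses)}")
print(f"procedures:      {len(bundle.procedures)}")
print(f"true adjuvant cohort:  {n_adj}")
print(f"true recurrent cohort: {n_rec}")

# show the first recurrent patient's timeline
pid = next(p for p, t in sorted(truth.patients.items()) if t.in_recurrent)
t = truth.patients[pid]
print(f"\npatient {pid}: era {t.era}, adjuvant {t.adjuvant_regimen}, "
      f"{t.recurrence_timing} recurrence, {t.tmab_group}")
for line in t.lines:
    kind = "adjuvant" if line.line_index == 0 else f"{line.line_index}L"
    print(f"  {kind:>8}: {line.regimen_label:<14} {line.start} -> {line.last_admin} "
          f"({line.end_reason}, event={line.event_observed})")
# Each line is a continuous episode of one regimen; the end reason says
# whether it closed by a >120-day silence, a new agent, death, or censoring.
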