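"""Derive the adjuvant and recurrent cohorts and print the attrition flow.

Every patient not entering a cohort carries exactly one exclusion reason —
the first failing rule in the documented order — so the flow table
reconstructs a patient-disposition diagram.
"""

from gclot import SimulationParams, StudyConfig, default_catalog, exclusion_flow, run_pipeline, simulate_cohort
from gclot.cohorts import ADJUVANT_RULE_ORDER, RECURRENT_RULE_ORDER

config, catalog = StudyConfig(), default_catalog()
bundle, _ = simulate_cohort(SimulationParams(n_patients=400, seed=7), config, catalog)
res = run_pipeline(bundle, catalog, config)

print("adjuvant cohort flow:")
for rule, n in exclusion_flow(res.adjuvant_cohort, ADJUVANT_RULE_ORDER):
    print(f"  {rule:<36} {n:>4}")
print("recurrent cohort flow (from adjuvant members):")
for rule, n in exclusion_flow(res.recurrent_cohort, RECURRENT_RULE_ORDER):
    print(f"  {rule:<36} {n:>4}")
# The counts sum to the bundle size (top) and to the adjuvant-member count
# (bottom); "included" rows are the cohort sizes used downstream.
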