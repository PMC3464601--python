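"""Generate a synthetic admitted-episodes cohort with ground truth.

Each person aged 65+ with a fall-related admission gets one or more
episodes; hip-fracture events spawn transfers, readmissions and deaths
with configured probabilities.
"""

from hddlink import SimulationConfig, simulate_cohort

cfg = SimulationConfig(n_persons=2000, seed=42)
episodes, truth = simulate_cohort(cfg, seed=42)

print(f"episodes:            {len(episodes)}")
print(f"persons:             {len(truth.persons)}")
print(f"true incident events: {len(truth.events)}")
second = truth.events["is_second"].sum()
fractured = truth.events["person_id"].nunique()
print(f"second fractures:    {second} ({100 * second / fractured:.1f}% of "
      "fractured persons — the configured repeat-fracture risk)")
print("\nepisode roles (how multiple counting arises):")
print(truth.episodes["role"].value_counts().to_string())
# 'index' rows are true incident admissions; every other fracture-chain row
# is an episode an unlinked count could mistake for a new case.
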