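"""Apply the study's eligibility rules and assemble the analysis table.

Participants must be 65 or older with MMSE >= 20 and enough valid sensor
days; lifestyle features are averaged per participant over valid days and
joined with demographics, comorbidities and the MMSE outcome — the
17-variable table every downstream stage consumes.
"""

import cogsense as cs

config = cs.CohortConfig(n_participants=12, days_per_cycle=8, cycles=1, seed=21)
cohort = cs.simulate_cohort(config)
daily = cs.score_cohort(cohort.epochs)

table, excluded = cs.build_feature_table(cohort.participants, daily, min_valid_days=7)
print(f"{len(table)} eligible participants, {len(excluded)} excluded")
if len(excluded):
    print("Exclusions (participant, reason):")
    print(excluded.to_string(index=False))

print("\nAnalysis table (lifestyle columns are per-day averages):")
show = ["participant_id", "age", "mmse", "walking_steps", "conversation_time", "tst", "sleep_efficiency"]
print(table[show].round(2).to_string(index=False))
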