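"""Screen selected variables for confounding by coefficient change.

Nested OLS models (unadjusted vs adjusted for age, gender, education) are
compared per lifestyle variable: a coefficient change beyond +/-200%, a sign
reversal, or a newly added variable marks it as confounded and removes it.
In the synthetic cohort WASO is the planted true positive — its crude
association with MMSE is a sign-flipped artefact of age.
"""

import cogsense as cs

config = cs.CohortConfig(n_participants=2000, seed=17)
table, _ = cs.simulate_feature_table(config)
table = cs.eligible_table(table)

selected0 = ["walking_steps", "conversation_time", "heart_rate", "tst", "waso"]
selected1 = selected0  # same lifestyle set enters the adjusted model here
screen = cs.screen_confounding(table, selected0, selected1, model_id=1)

print(f"{'variable':20s} {'unadjusted':>11s} {'adjusted':>10s} {'change %':>9s}  flags")
for c in screen["changes"]:
    pct = f"{c.percent_change:+.1f}" if c.percent_change is not None else "undef"
    flags = ",".join(c.reasons) or "-"
    print(f"{c.variable:20s} {c.unadjusted_coef:+11.5f} {c.adjusted_coef:+10.5f} {pct:>9s}  {flags}")

print(f"\nSurviving variables: {screen['surviving']}")
print(f"Excluded as confounded: {screen['excluded']}")
print("A sign reversal means the crude association pointed the wrong way entirely —")
print("here WASO's negative crude coefficient was induced by age, not by sleep itself.")
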