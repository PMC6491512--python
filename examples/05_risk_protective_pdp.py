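"""Classify lifestyle variables as risk/protective from PDP curves.

A forest fit on the adjusted-model predictors yields a partial-dependence
curve per variable (substitute each observed value into every row, predict,
average). The sign of corr(grid, marginal prediction) labels the variable;
a persistent slope reversal of the smoothed curve yields a threshold and a
half-range protective interval — the signature of an inverted-U effect.
"""

import cogsense as cs
from cogsense.forest import ForestSpec
from cogsense.variables import MODEL_POOLS

config = cs.CohortConfig(n_participants=800, seed=29)
table, _ = cs.simulate_feature_table(config)
table = cs.eligible_table(table)

forest = cs.fit_forest(table, MODEL_POOLS[1], "mmse", ForestSpec(seed=29))
print("variable             label        corr   threshold   protective range")
for var in ["walking_steps", "heart_rate", "conversation_time", "tst"]:
    curve = cs.partial_dependence(forest, table, var, n_grid_cap=128)
    cls = cs.classify_factor(curve)
    thr = cs.detect_threshold(curve)
    rng_txt = "-"
    if thr is not None:
        lo, hi = cs.protective_range(curve, thr)
        rng_txt = f"[{lo:.0f}, {hi:.0f}]"
    print(f"{var:20s} {cls.label:11s} {cls.correlation:+.3f}   "
          f"{'-' if thr is None else format(thr, '.1f'):>9s}   {rng_txt}")

print("\nGenerator truth: steps and heart rate are linearly protective; sleep and")
print("conversation follow inverted-U effects peaking at 450 and 300 min/day, so a")
print("detected threshold near those values is a correct recovery. A threshold at")
print("the sparse upper tail of an otherwise monotone variable (as can happen for")
print("steps) reflects forest noise where data are thin, not a real reversal —")
print("read thresholds together with the curve and the data density.")

seg = cs.segmented_correlation(table, "conversation_time", "walking_steps", 300.0)
print("\nSteps vs conversation (normal-transformed), split at 300 min:")
for side in ("below", "above"):
    s = seg[side]
    print(f"  {side}: n={s['n']}, slope={s.get('slope', float('nan')):+.3f}, p={s.get('p_value', float('nan')):.3g}")
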