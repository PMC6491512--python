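# Methods

This note records the models, defaults and numerical choices behind
`cogsense`, and what the synthetic validation does and does not establish.

## Scoring model

Scoring consumes 1-minute epochs (movement magnitude, step count, voice
sound-frame count, pulse count) on the local clock, 1440 per calendar day,
with no daylight-saving transitions in synthetic calendars.

* **Wear.** Minutes inside a run of ≥ `nonwear_run_min` (default 60)
  consecutive zero-pulse minutes are non-worn; missing epochs are treated
  as non-worn. The 60-min run length is a package choice: the underlying
  idea — sustained absence of pulse detection means the band is off — does
  not prescribe a cutoff.
* **Sleep window.** 18:00 → 5:59, anchored to the *evening's* date, so a
  night is unambiguously assigned across midnight. The last evening of a
  recording block needs the following morning; without it the window is
  scored on available minutes and flagged incomplete (such days are not
  valid for averaging).
* **Sleep events.** Onset = start of the first run of ≥ 20 consecutive
  motionless minutes; end = last minute of the last such run (the onset
  rule mirrored — the end itself is a package decision, as only onset and
  awakenings have stated definitions); awakening = run of ≥ 20 moving
  minutes strictly inside (onset, end); WASO = all moving worn minutes
  strictly inside; TST = (end − onset) − WASO; efficiency = TST/(end −
  onset), reported as a fraction in (0, 1]. Non-worn minutes inside the
  sleep interval count as neither sleep nor wake and are absorbed into TST
  via the identity; they are rare unless non-wear simulation is enabled.
* **"Without movement"** means magnitude ≤ `motionless_eps` (default 0;
  the generator encodes stillness as exactly 0). Real accelerometer counts
  would need a small positive ε; the knob exists for that purpose.
* **Naps** are motionless runs of ≥ `nap_block_min` (default 20, mirroring
  the nocturnal block rule; configurable) between 6:00 and 17:59.
* **Conversation** minutes have ≥ 5 sound frames — the strict reading of
  "more than four frames per minute"; `conversation_min_frames=4` gives
  the inclusive reading.
* A day is **valid** when worn ≥ 1080 minutes and its sleep window is
  complete.

## Synthetic cohort generator

The generator emulates a community cohort of adults ≥ 65 wearing the band
~8 days per quarter for 4 quarters. It is the package's test bed: its
defaults define the conditions under which the pipeline's recovery
properties are demonstrated.

**Demographics** follow the summary marginals of such cohorts: age
N(73.8, 5.8²) years, 62.9% women, education N(11.8, 2.1²) years (clipped
6–20), BMI N(23.2, 3.1²), smoking/alcohol 3-level codes, hypertension
50.2%, diabetes 13.3%, hypercholesterolemia 32.9%.

**Lifestyle features** (per-participant true daily means): steps
5452.9 ± 2778.0/day, conversation 219.7 ± 86.3 min, heart rate
64.7 ± 6.3 bpm, TST 408.4 ± 69.1 min, WASO 22.1 ± 14.1 min, nap
48.7 ± 39.3 min. The quoted SD is the *between-person* SD of
period-averaged values; confounder contributions are subtracted from its
square so the marginal SD matches regardless of confounding strength.
Day-to-day (within-person) SDs are package choices of realistic magnitude
(e.g. steps 1200/day, TST 35 min) — they matter only through averaging
noise ∝ 1/√(n days).

**Confounding** is injected on both a lifestyle feature and MMSE: per year
of age −80 steps, +1.8 min WASO, +0.5 min TST and −0.12 MMSE points; per
education year +3 conversation min and +0.15 MMSE; women +15 conversation
min (no direct MMSE effect).

**Outcome.** MMSE = round(base + Σ effects + Σ confounder terms +
N(0, noise_sd²)) clipped to [0, 30], base 26, noise 1.5. The noiseless
expectation is retained as ground truth. Default effects: steps +1.0 and
heart rate +0.7 MMSE points per between-person SD (linear); TST and
conversation inverted-U Gaussian bumps h·exp(−(x−p)²/2w²) with
(h, p, w) = (1.8, 450 min, 90 min) and (1.5, 300 min, 100 min); WASO a
weak +0.22/SD linear term. Magnitudes were set so that the steps effect
dominates and conversation/TST carry comparable, clearly detectable
curvature at the study's scale (~800 participants), matching the
qualitative ordering the pipeline is meant to recover; the base/noise
choice reproduces the strong ceiling of real MMSE data (~27% of scores at
30, median 28–29).

Why WASO has a weak *positive* direct term: a variable whose association
is induced **purely** by a confounder has a true adjusted coefficient of
exactly 0, so the coefficient-change rule (flag when |Δ| > 200% or the
sign reverses — note full attenuation is only −100%) fires on it with
probability ≈ ½ (the sign of a null estimate is a coin flip). The
detectable — and empirically observed — confounding signature is
*overshoot*: a weak direct association masked and sign-flipped by
confounding, so that adjustment reverses the sign and often exceeds the
200% band. The generator plants exactly that structure: WASO's crude
coefficient is negative (an age artefact), its adjusted coefficient weakly
positive.

**Epoch synthesis.** Each day places one contiguous nocturnal sleep block
(onset ≈ 22:30 ± 40 min) with optional inserted wake bouts (one long
≥ 20-min bout with probability WASO-mean/44, plus short 3–12-min bouts),
0–2 daytime nap bouts, conversation minutes and multinomially scattered
steps in daytime wake minutes, and pulse counts (wake ≈ HR+2, sleep ≈
HR−8). Construction guarantees the scorer's event definitions recover the
recorded layout exactly on clean days: wake minutes always move, bouts are
separated by ≥ 20 sleep minutes, naps sit inside the daytime window. The
distributions of wake-bout and nap-bout counts/lengths are pragmatic
choices — no source specifies them.

**Two fidelity levels.** Epoch streams feed the scoring round-trip tests;
cohort-scale experiments (selection, confounding, PDP recovery) use a
feature-level fast path that draws the averaged table directly
(true mean + N(0, daily_sd/√n_days)), with sleep efficiency =
TST/(TST + WASO) and awakening count = Binomial(n days, WASO-mean/44)/n
days. Both levels share the same participant and outcome model. MMSE
depends on *true* means; observed features add averaging noise, so
estimates carry the (negligible at 32 days) attenuation real averaging
would.

**What the generator does not emulate:** seasonality beyond cycle
scheduling, longitudinal cognitive change, measurement error structure of
real accelerometry (baseline drift, posture artefacts), device-level
signal processing, or selective non-wear. Passing recovery tests
demonstrates the pipeline's correctness and power under this explicit
model, not performance on any real cohort.

## Forest and selection

scikit-learn's `RandomForestRegressor` with ntree = 500 and
mtry = ⌊p/3⌋ (minimum 1), deliberately untuned. Bags are the classic
n-samples-with-replacement bootstrap (≈ 63.2% unique in-bag, the "two
thirds in the bag" convention of regression forests). Importance is the
forest's node-impurity measure (total decrease in node sum-of-squares,
normalised per the library convention); ties break by canonical table
order so rankings are deterministic. Top-N selection refits a forest on
the top 1..p variables using a single stratification-free 90/10 split and
picks the N with the lowest test RMSE (smallest N on ties). A single split
is high-variance, so `topn_select(n_splits=S)` offers a median-over-splits
variant; the default (S = 1) matches the study design being reproduced.
Categorical codes (gender, smoking, alcohol, comorbidities) enter as
numeric ordinals, matching the coding of the analysis table.

## Confounding screen

Percent change = 100·(β_adj − β_unadj)/β_unadj on raw coefficients (the
formula is scale-invariant per variable); undefined when β_unadj = 0, in
which case only sign reversal / newly-added apply. "Newly added" is
operationalised through the selection stage: a variable in the adjusted
model's selected set but not the unadjusted model's (fixed-covariate
linear fits cannot add variables by themselves). The flag threshold is
|Δ| > 200%, which together with sign reversal reproduces the worked
overshoot exclusion pattern described above.

## Partial dependence and thresholds

The PDP grid is the sorted unique observed values, thinned to ≤ 256
equally spaced quantiles when unique values exceed the cap (tractability;
the exact-unique rule is kept below the cap). Marginal predictions are
computed by substitution-and-average; the implementation batches grid
values per predict call, which changes neither per-row tree traversal nor
the per-grid mean — it is verified *exactly equal* to the one-value-at-a-
time oracle in the tests.

Classification: Pearson r over (grid, marginal prediction); |r| < 0.05
(configurable dead zone) is reported indeterminate rather than assigning a
coin-flip label to a flat curve. Threshold detection smooths the curve
with a centred 5-point moving average (shrinking at the edges), then
accepts the global interior extremum if the first differences hold one
sign for ≥ 2 consecutive points before it and the opposite sign for ≥ 2
after (plateaus return the plateau centre); monotone curves yield none.
The protective range is the maximal contiguous grid interval around the
peak on which the smoothed curve stays ≥ min + ½·range. The window and the
half-range rule are package choices — reported protective ranges in the
literature come without a stated derivation — and both are parameters.
Thresholds in the sparse tail of a near-monotone variable should be read
against data density (see `examples/05`).

## Transform, contribution, accuracy

The normalising transform is the Blom rank-inverse-normal score
Φ⁻¹((rank − 3/8)/(n + ¼)) with average ranks on ties — deterministic,
strictly monotone, and named in every report (sources that "transform to
the normal distribution" rarely say how). Contribution regression reports
raw estimates on transformed predictors *and* fully standardised
coefficients, since it is usually unstated which is meant. The accuracy
comparison shares the 90/10 split convention and seed with the selection
stage; MSE = RMSE² holds exactly by construction.

## Experiment sizes

Recovery experiments use 20 seeded cohorts of 800 participants (the scale
of the motivating study), with forest/split/cohort seeds spawned from one
base seed. The confounding calibration — an OLS-only coefficient
comparison — uses cohorts of 2000 so that the screen's sampling error is
small relative to the coefficient under test; it still runs in seconds
per seed. The scoring round trip uses ~1,000 epoch-level days (32
participants × 32 days). These sizes are the package's validation
defaults; all are arguments.

## Known limitations

* Sleep end has no external definition; symmetric-rule scoring can differ
  from proprietary device algorithms.
* The single-split top-N rule is noisy by design fidelity; use
  `n_splits > 1` for stable selection in applied work.
* The threshold detector reports one global reversal; multi-modal curves
  and reversals within 2 grid points of the edges are not detected.
* The confounding rule itself (inherited from the reproduced design)
  cannot reliably detect *pure* confounding, which fully attenuates a
  coefficient (−100% change, unflagged); it detects overshoot and
  sign-reversal patterns.
* MMSE ceiling effects attenuate all fitted coefficients relative to
  generator ground truth; this is realistic and intended, but means
  estimated effect sizes are biased toward zero near the top of the scale.
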