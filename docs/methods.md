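# Methods

## Data model

A session is three aligned position series — head, left hand, right
hand — on a uniform grid of times k·Δt, k = 0…floor(duration/Δt), in
meters with y up and (x, z) the floor plane. Defaults are Δt = 0.5 s
and duration = 300 s, giving 601 samples per device. Raw log rows are
snapped to the nearest grid time (tolerance Δt/2; exact midpoints
resolve to the earlier sample; the last of duplicate rows wins). The
coordinate convention is fixed rather than configurable to prevent
silent unit errors downstream of the area computation.

Tracking dropouts: interior gaps of at most `max_gap` (default 2)
consecutive missing samples per device are filled by per-coordinate
linear interpolation between the flanking observations; longer gaps and
gaps at either session boundary fail validation, and the pipeline
excludes such subjects with a logged reason (or aborts under
`--strict`). This is a declared convention of the package: short
interpolable dropouts are routine for consumer headsets, while
extrapolating boundary gaps would fabricate data.

## Kinematic variables

All seven variables derive from per-step Euclidean displacements
d_k between consecutive grid positions (forward differences — speeds
are step displacements over Δt, not central differences). Design
choices that were genuinely open and are fixed here:

* **Device aggregation.** Speed and acceleration average the three
  devices with equal weight; total distance sums them. Sums and means
  use exact (compensated) summation, so relabeling the two hands cannot
  change any value even in the last bit.
  A consequence of equal weighting is that total distance equals
  3·(L−1)·Δt·average speed identically, so the two variables are
  perfectly collinear in any cohort; see "Stepwise selection" below
  for how the selection procedure handles that.
* **Area occupied** is the convex-hull area of the head's floor-plane
  projection (the head best proxies body placement; the convex hull is
  the standard occupancy measure). Fewer than 3 distinct points, or
  collinear points, give area 0.
* **Movement/stillness** tests use the maximum per-step displacement
  over the three devices, so that any limb movement counts. A step
  "moves" when that maximum exceeds threshold₁ (default 0.05 m per
  step) and is "still" when it is at most threshold₂ (default 0.02 m
  per step; threshold₂ ≤ threshold₁ enforced). The defaults separate
  deliberate motion from tracking jitter at consumer-headset noise
  levels (millimeters per sample); both are echoed into every results
  file.
* **Movement frequency counts bout onsets** (transitions into the
  moving state, session start included), not moving samples, so it is
  a distinct quantity from 1 − stillness. It is normalized by spanned
  time, (L−1)·Δt, in minutes.
* **Acceleration** uses absolute speed changes |v_{k+1} − v_k|/Δt,
  making it a nonnegative movement-intensity measure rather than a
  signed one.

Invariances verified by the test suite: translation and rotation about
the vertical axis leave all seven variables unchanged; scaling all
coordinates by c > 0 (with thresholds scaled likewise) scales
speed/acceleration/distance by c and area by c²; time reversal
preserves everything except the bout-onset count; stillness time is
monotone in threshold₂ and the event count anti-monotone in threshold₁.
All variables also match independent naive-loop oracle implementations
to 1e−9 relative tolerance on random sessions.

## Questionnaire scoring

Scores are plain item sums; subscale maps are configuration data with
published-instrument defaults (ADHD-RS: odd items inattention, even
hyperactivity; RPQ: the published 11 reactive / 12 proactive split).
The ARI symptom total sums the first 6 items by default, excluding the
7th impairment item — the convention under which the total ranges 0–12
— and is switchable to 7 items (`ari_items_in_total`). Descriptive
statistics use the sample SD (n−1).

## Inference

* **Correlation screen.** All 7×11 feature–measure pairs, Pearson r
  with a two-sided p from the t reference distribution with n−2 df,
  listwise complete cases per pair. Pairs with fewer than 3 cases or a
  constant vector are reported as not computable rather than dropped.
  No multiple-testing correction is applied (deliberately, matching
  screen-then-model practice); the number of tests performed is
  recorded in the manifest and the model report.
* **Stepwise selection** is backward elimination with re-entry: start
  from the full model; repeatedly remove the predictor with the
  largest p > p_remove (default .10); when none qualifies, re-enter
  the excluded predictor with the smallest add-one p < p_enter
  (default .05); stop when stable. p_enter ≤ p_remove is enforced to
  prevent cycling, a `max_steps` guard (default 100) bounds the loop,
  and ties on p break by predictor column order, making selection
  fully deterministic. Pure backward elimination is available via
  p_enter = 0. An empty final model is a valid outcome, flagged and
  rendered as an em-dash row in reports.
  Perfectly collinear predictors (rank-deficient full designs — which
  the package's own feature set produces, see above) are pre-dropped
  in column order before selection and recorded in the step trace; the
  trace also records the preliminary full-model VIFs and every
  removal/re-entry with its p at decision time, so the selection path
  is auditable.
  When n ≤ k+1 the start set is the largest fittable model by marginal
  |r| ranking (recorded in the trace); with n < 3 the procedure
  refuses, and the orchestrator records a per-outcome refusal instead
  of aborting the other stages.
* **VIF** is 1/(1−R²_j) from regressing predictor j on the other
  retained predictors (with intercept), computed after selection; a
  single retained predictor has VIF 1 by convention, perfect
  collinearity reports infinity, and values ≥ 5 are flagged.
* R² is the plain coefficient of determination (not adjusted).

## Synthetic cohorts

The generator emulates the shape of a 45-child VR study: per subject a
latent scalar trait h ~ N(0, trait_sd²) drives both movement intensity
and symptom severity — the minimal structure consistent with one or two
kinematic variables explaining each outcome.

Movement is a two-state (still/moving) Markov bout process on the grid.
While moving, the head advances toward uniformly sampled waypoints in a
4 m × 3 m room (half-widths 2.0 and 1.5 m) at speed
`speed_base`·exp(`speed_loading`·h) (defaults 0.35 m/s and 0.35/unit h,
a child's indoor walking pace); positions are clamped to the room, which
bounds the occupied area by the room area. The per-step logit of
leaving stillness is `still_rate_base` + `still_rate_loading`·h
(defaults −2.2, 0.6: still bouts of ~5 s at h = 0, shorter for high-h
children) and of stopping is `move_stop_base` + `move_stop_loading`·h
(defaults −1.5, −0.4). Bout dynamics, rather than pure diffusion, let
movement frequency and stillness vary partly independently of speed.
Hands ride at a fixed-direction offset of length `hand_offset`
(default 0.45 m) plus slow AR(1) wander. Gaussian tracking jitter
(`noise_sd`, default 3 mm per sample) and AR(1) postural sway
(stationary SD 2 cm, φ = 0.95) overlay everything; at these levels
still-state steps stay almost surely below threshold₂ while moving
steps (≈0.18 m) sit far above threshold₁.

Items are ordered-categorical draws: latent location
`item_loading`·h + `item_difficulty` plus standard logistic noise, cut
at fixed evenly spaced thresholds; participant (self-report) noise is
inflated ×1.6 so parent reports track h more tightly. Per-instrument
difficulties (−0.4/−0.6/−1.0) put h = 0 subjects near mid-range scores.
The default `item_loading` = 0.46 was set once with the package's
calibration utility so the default cohort's speed–hyperactivity
correlation lands mid-range of the effect sizes such studies report
(r ≈ 0.55). `calibrate_item_loading` bisects the loading against a
fixed large probe cohort (feature values are simulated once, since they
do not depend on the loading) to hit any target feature–score
correlation, enabling effect-recovery studies with a planted population
ρ*.

Everything is reproducible from the config seed; a cohort simulated
twice with the same config is bit-identical, end to end through the
report files.

What the generator does **not** emulate: biomechanics (gait, reach
kinematics), avatar interaction, age/sex structure, informant
disagreement beyond noise inflation, per-subscale difficulty (proactive
aggression scores, near-floor in real cohorts, are mid-range here), or
tracking dropouts. Passing tests therefore demonstrate the pipeline's
statistical behavior under a clean single-trait data-generating
process, not clinical validity on real children.

## Test problem sizes and numerical choices

Statistical properties are checked at sizes chosen to make the checks
sharp yet quick: planted-predictor recovery uses 100 replicates at
n = 500 with a planted partial R² ≈ 0.33 (retention required in ≥95);
screen null calibration uses 13 null cohorts of n = 400 (1001 tests,
99% binomial bounds around α = .05); generator effect recovery uses a
ρ* = 0.5 calibration and 100 replicate cohorts at n = 400 (±0.1 in
≥95). Random draws are fixed-seeded throughout. Feature-versus-oracle
comparisons use 1e−9 relative tolerance; OLS is checked against the
normal equations at 1e−8; the 4-point Pearson case is checked against
the closed-form 2-df t CDF.

## Known limitations

* The exact-collinearity of average speed and total distance is a
  consequence of the equal-weight aggregation convention; analyses that
  need both as separate predictors require a different speed definition
  (e.g. over moving time only), which this package intentionally does
  not offer.
* Stepwise selection at n = 45 is unstable between correlated
  predictors; the package reports the selection trace rather than
  pretending otherwise.
* No rotation/orientation handling: hand offsets in the generator are
  world-frame, and features use positions only.
* The screen's per-pair error rate is calibrated, but no familywise
  control is attempted across the 77 tests.
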