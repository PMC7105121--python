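# Methods

This note documents the models, estimators and numerical choices behind
`flywalk`, and what the synthetic-data validation does and does not show.

## Setting

A single fly walks between two plates in a circular arena of radius
R = 40 mm, filmed at 30 Hz for 6 minutes. During the last 3 minutes a
central region is lit (full intensity to 10 mm, linear ramp to zero at
13 mm); the behavioural *light border* used throughout is b = 0.3 R
= 12 mm. Analyses split each track at the *first entry* — the first frame
after light-on with r < 12 mm — into a `before` scenario and, afterwards,
`during_in` / `during_out` by current position.

## Kinematics

Displacements between consecutive frames give speed s (mm/s) and movement
direction; the movement angle φ is the body orientation minus the movement
direction, thrust and slip are s·cos φ and s·sin φ, and yaw is the wrapped
frame-to-frame orientation change. Path curvature k (deg/frame) is the
rotation of the path's normal vector, where the tangent at a frame averages
the unit displacements of its two adjacent steps; angle differences are
taken via atan2 of the 2-D cross/dot products so they never jump by 360°.
Counter-clockwise turning is positive for both k and yaw. Frames adjoining
a step shorter than 10⁻⁶ mm/s × Δt have undefined direction-dependent
quantities (NaN); cumulative sums treat them as zero.

## Four-state segmentation

Frames within 1.5 mm (half a fly length) of the wall are `boundary`;
remaining frames slower than 0.5 mm/s are `stop`. The rest are split by a
weighted binarization: b₁ = 1{|k| > 13.843 deg/frame},
b₂ = 1{|dk| > 4.080 deg/frame²}, w = 0.890·b₁ + 0.739·b₂, smoothed with a
centered moving average; frames with smoothed w > 1.365 are `sharp_turn`,
below 0.230 `curved_walk`, and in-between frames attach to the temporally
nearest stretch (> 5 frames) of either class, ties going to the turn.

Three numerical choices matter and were settled by measuring ground-truth
frame recovery on synthetic cohorts:

- **dk stencil.** dk is a one-sided (forward) difference. A centered
  difference straddles two frames, which leaks turn curvature one frame
  into the flanking walk and doubles the width of every low-|dk| episode
  inside a turn; both effects cap recovery noticeably below the one-sided
  stencil.
- **Smoother width.** The moving average on w spans 3 frames. A 5-frame
  average makes the 1.365 threshold unreachable for turns shorter than
  about 12 frames (a single fully-binarized frame contributes at most
  1.629/5 ≈ 0.33 to the window mean).
- **Alignment.** Each step's speed and curvature are attributed to the
  frame the step *arrives at*, matching the convention that a state's label
  covers the motion it produced. This removes a systematic one-frame offset
  at walk/stop and walk/turn transitions.

With these choices, segmentation recovers ≥ 95% (typically ~97%) of
ground-truth frame labels on noise-free cohorts whose walks stay below
~3 deg/frame and whose turns sustain ~25+ deg/frame. Residual errors are
one-to-two-frame ambiguities at state transitions, which are genuinely
undecidable at 30 Hz.

Turn/walk separability is summarized by a cross-validated logistic
regression on segment mean |k| (accuracy and AUROC both reported, since
either may be quoted as a single "confidence" figure).

## State distributions

Each state × scenario cell is summarized by a joint density over its
defining parameters (stop and turn: duration × signed total curvature;
walk: speed × duration × mean curvature; boundary: duration × signed arc
angle, stored in the segment table's total-curvature column). Densities
are Gaussian-kernel KDEs with Scott plug-in bandwidth; sampling draws a
data point and adds kernel noise, rejecting draws that violate the support
(durations > 0, speeds ≥ 0). The diffusion-type KDE cited for the original
analysis is not available here; at these sample sizes the fitted moments,
not fine bandwidth detail, drive every downstream result. The
`(during_in, boundary)` cell is structurally empty — the wall lies outside
the light zone — and is skipped rather than treated as an error. Walk
termination (turn vs stop) uses the empirical segment-count ratio per
scenario; boundary circling direction is a per-scenario Bernoulli.

## WTSB simulator

A synthetic fly starts at the center heading along +x and always begins
with a walk. Walks integrate one frame (1/30 s) at a time with constant
sampled speed and per-frame curvature; they end at the sampled duration
(drawing a turn or stop) or pre-emptively at the wall margin (boundary).
Sharp turns carry no speed in their joint pdf, so they reuse the preceding
walk's speed; by default they run straight for half the sampled duration,
reorient instantaneously by the sampled total curvature, and run straight
for the second half. Stops hold position and reorient at the end; with a
creep option (used by the ground-truth generator) they instead drift at
0.2 mm/s along the gradually rotating heading so the reorientation is
visible to path-curvature measures, as it is in tracked flies whose
"stops" are sub-threshold motion. Boundary bouts advance along the wall by
the sampled arc and exit toward the center ± uniform(−10°, 10°). All
randomness flows through one generator per fly seeded from (seed, fly id);
runs are bit-reproducible.

**Border choice** (WTSB+BC+TB) applies to the first two turns after a
light-border crossing: with probability (1 − baseline) × P(≥ n turns |
track type), the current walk is terminated in a turn when the fly's
radius first crosses a target drawn from the rectified excess density for
its track type; otherwise (and whenever the target is never reached) the
base termination applies. The baseline of 0.2 keeps a fraction of turns on
the base process. Turn counting is track-consistent: a turn belongs to the
crossing track containing its curvature peak, and wall-truncated turns
still consume a turn index.

**Turn bias** chooses the direction of those same turns. Both candidate
reorientations (±|total|) are evaluated against the estimator's own inward
event (θ_after < θ_before with u = −p₂); when exactly one candidate
realises it, that candidate is chosen with probability = bias, otherwise
geometry forces the class and a fair coin picks the side. This targets the
measured quantity directly; choosing "the candidate with the smaller angle
to the inward vector" instead distorts the realized inward fraction
whenever the closer candidate overshoots past the radial direction. A
residual distortion of about bias × P(γ < Δ/2) — turns whose magnitude Δ
exceeds twice the approach angle γ, where *no* direction rule can produce
an inward outcome — is irreducible; the bias-validation probe therefore
uses small turns (~6°) to keep it to a couple of percent.

**Selection** mirrors the behavioural inclusion rules: a fly is kept if in
both the before and during periods it reaches 1.1× the light radius and
comes within 0.9× of it, and if its first-entry time is within the 85th
percentile of a supplied reference set.

## Border-turn detrend

Crossing tracks start at the border by construction, so their raw
turn-location pmfs are skewed toward it. Under uniform start radii and
exponential(λ) radial displacement per walk, the expected turn-location
density for border-crossers is the closed form

    T(r) = e^{λ(r−b)} − e^{λ(r−1)}   for 0 ≤ r ≤ b   (inward crossers)
    T(r) = e^{−λ(r−b)} − e^{−λr}     for b < r ≤ 1   (outward crossers)

and 0 elsewhere. Each branch carries its own normalization, so T is
generally discontinuous at r = b; downstream use normalizes over the grid
and is invariant to positive rescaling. The closed form is verified in the
tests against direct quadrature of the defining convolution (≤ 10⁻⁶ at 100
grid points) and against a 10⁵-sample Monte-Carlo simulation of the
crossing model (total-variation distance < 0.02 on 50 bins). λ is
estimated by maximum likelihood (1/mean |Δr|) from per-walk radial
displacements in before-period crossing tracks. The border-choice
densities are f = max(0, P − T_norm)/Σ max(0, P − T_norm) per track type,
with P(≥ n turns | track) estimated from per-track turn counts.

## Synthetic ground truth

The generator drives the simulator with fully parametric distributions:
lognormal walk speeds (median 8 mm/s before; 4–5 mm/s during light,
reflecting the slow-down inside), gamma durations (walks ~1 s, stops ~1 s,
wall bouts ~7 s), Gaussian walk curvature (sd 2 deg/frame), and sharp
turns of |total| ~ N(100°, 30°) truncated at 40° over ~0.3 s — per-frame
curvature well above the 13.8 deg/frame level that separates turns from
walks, as the fitted segmentation thresholds imply for real flies.
Positional noise defaults to 0.15 mm, the tracking error scale. Three
special-purpose regimes exist:

- `recovery_spec` — noise-free, walks ≤ 3 deg/frame, turns sustaining
  ~36 deg/frame with a slow (period-8) ripple. The ripple exists because
  the fitted classifier requires *both* |k| and |dk| above threshold
  inside turns; its period is kept longer than the dk stencil so the
  inevitable |dk| dips at ripple extrema stay isolated single frames.
- `bias_probe_spec` — small turns (~6°) and strongly curved walks, the
  regime where the direction choice fully determines the inward/outward
  class (see above).
- interior (slow-walker) cohorts — flies that never reach the wall, used
  for renewal-bookkeeping and cumulative-curvature ablation checks, since
  wall entry/exit in the simulator kinks the heading outside the three
  modelled reorientation types.

What passing these validations shows: the estimators invert the generative
model they assume, at realistic sample sizes, through the full pipeline
(simulate → segment → fit → estimate). What they do not show: robustness
to real tracking artefacts (head/tail swaps, reflections at the wall,
nonstationary behaviour within a scenario), none of which the generator
emulates.

## Problem sizes

Validation runs use 50 flies (segmentation recovery), ~1000 first-two
turns per programmed bias (bias recovery), 10,000 one-minute flies
(containment), 100 six-minute flies (state occupancy), and 200 flies per
arm (attraction comparison); these sizes put Monte-Carlo error comfortably
inside each check's tolerance.

## Known limitations

- The simulator's wall entry/exit and stop reorientation (without creep)
  produce heading discontinuities that path-curvature measures cannot see;
  cumulative-curvature comparisons are therefore restricted to interior
  tracks.
- Scenario-level state distributions cannot express within-scenario
  spatial structure (e.g. turns sharpening specifically at the border);
  border choice and turn bias capture the location and direction of the
  first two post-crossing turns but not magnitude changes.
- The inward-turn estimator's closed-loop accuracy degrades for large turn
  magnitudes for geometric reasons quantified above; empirical bias
  estimates on large-turn cohorts are faithful descriptions of the
  executed turns, but programming a target bias into such a cohort is only
  approximately possible.
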