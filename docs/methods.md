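# Methods

`rcptvfa` quantifies *physical engagement* versus *task performance* in the
rodent Continuous Performance Test (rCPT), a touchscreen go/no-go attention
task. The question the pipeline answers is whether a within-session decline
in performance (the vigilance decrement, or time-on-task effect) is
explained by the animal ceasing to look at the screen, or by a change in
perceptual/decisional processing while still looking. It does this by
joining two data streams: the operant event log (stimulus onsets and the
four trial outcomes) and a markerless-pose keypoint track of the head,
from which a per-trial "oriented" flag and a per-bin orientation index are
derived and set against signal-detection metrics in the same time bins.

## Task model and simulator

A session is a sequence of trials. Each trial presents a target (S+) or
non-target (S−) stimulus; a touch within the **limited hold** (LH =
stimulus duration + 0.5 s post-stimulus interval) on S+ is a *hit*
(rewarded, 20 µL), on S− a *false alarm*; withholding yields a *miss* (S+)
or *correct rejection* (S−). False alarms trigger correction trials: the
non-target repeats until the agent withholds. Every outcome is followed by
an inter-trial interval (ITI); a centre touch during the ITI restarts it
and is the impulsivity numerator. Named presets encode the training
stages: Stage 1 (SD 10 s, ITI 2 s, every trial S+), Stage 2 (SD 5 s),
Stage 3 (SD 3 s → LH 3.5 s, ITI 5 s, S+ probability 0.5, 45 min, reward
cap 150) and the time-on-task (TOT) probe (Stage 3 stretched to 90 min,
cap 999 so the cap is never the stopping rule). Stage advancement is a
pure function over session summaries: ≥ 60 rewards in a 45-min session
(Stages 1–2); d′ > 0.6 on two consecutive sessions with ≥ 7 sessions
completed (Stage 3).

The simulated agent is intentionally the simplest generative family that
can produce a vigilance decrement with stable orientation: per-trial
Bernoulli outcomes with propensities drifting linearly in session time
(clamped to [0, 1]), log-normal response and reward-collection latencies
(response latencies resampled into the LH), a Bernoulli screen-orientation
policy with its own drift, and Poisson ITI touching. Defaults emulate a
trained animal in a TOT probe: hit propensity 0.65 falling 0.003/min,
false-alarm propensity 0.25 falling 0.001/min, orientation policy 0.92
with zero drift, ITI touch rate 0.02 s⁻¹. Misses and correct rejections
are timestamped at onset + LH (no touch occurred); hits and false alarms
at onset + drawn latency. Within a correction loop the false-alarm
propensity is reused; a forced exit after 25 correction trials (logged)
guarantees termination when the propensity clamps at 1. The simulator's
RNG draw order (stimulus, outcome, orientation, latencies, ITI gaps) is a
documented contract so an independent straight-line replay can verify the
state machine.

## Pose synthesis

One pose frame per video frame (default 720 × 480 at 30 fps; any positive
rate accepted) renders three keypoints — nose/top of head, left ear, right
ear — in image coordinates (origin top-left, y down, pixels). Head
position and heading follow Ornstein–Uhlenbeck walks (position about the
arena centroid, heading about the direction facing away from the screen);
only the oriented/not-oriented contract matters downstream, so any smooth
heading process would do. During the limited hold of a trial drawn
oriented, the gaze is aimed at the stimulus-segment midpoint; during a
non-oriented trial's LH it points directly away, and the head is kept in
a central region ≥ 1.5 segment-lengths from the screen wall so the whole
segment then sits far inside the blind sector. Artifacts are injected as
mutually exclusive per-frame labels: Gaussian coordinate jitter (1 px
default), outlier frames (one keypoint displaced 150–250 px, rate 0.02)
and low-likelihood frames (one keypoint's likelihood dropped to 0.2–0.85,
rate 0.02); clean likelihoods sit in [0.95, 1].

Ground-truth per-frame oriented/blind labels are computed from the
rendered (jittered, pre-artifact) keypoints by an *exact interval*
construction: the signed bearing to a segment point is continuous in the
segment parameter except at ±180° (where it stays blind), so the blind
indicator switches only where |bearing| crosses the lateral bound — a
linear condition with at most one root per boundary ray. This route is
deliberately independent of the sampling-based classifier used by the
analysis, so round-trip tests compare two different computations. After
labelling, each trial's realised oriented flag is reset to the OR over its
LH frames, which keeps the trial/frame ground truth consistent by
construction. What the generator does **not** emulate: perspective
distortion, grooming or rearing postures, occlusions, correlated
likelihood dips, or multi-animal scenes — so green tests certify the
analysis logic, not robustness to every failure mode of real pose
estimation.

## Keypoint quality control

Two filters, both evaluated on the full track so their order is
immaterial. (1) For each of the three inter-keypoint distances, z =
(Y − mean)/SD with the mean and **population** SD (N denominator) over all
frames; a frame is excluded when any |z| is strictly greater than 3. The
SD flavour is a choice (N vs N−1 changes z by < 0.1 % on real track
lengths); the oracle tests use the same flavour. A zero-variance series
excludes nothing. (2) A frame is excluded when any body part's likelihood
is strictly below 0.9. Excluded frames are dropped from orientation
analysis, never interpolated. Both thresholds are exposed
(`--z-threshold`, `--likelihood-threshold`); statistics are not recomputed
after the likelihood filter.

## Visual-field geometry

Head pose: origin = ear midpoint, gaze bearing = direction to the nose
keypoint; invalid when the nose is within 1e-6 px of the origin (counted
and dropped). The bearing sectors are frontal (|θ| ≤ 20°), lateral left
and right (20° < |θ| ≤ 103.4°, side by the sign of θ, positive = animal's
left = counter-clockwise sense of atan2 in image coordinates) and blind
(|θ| > 103.4°). The configured angles are read as **half-widths** (40°
binocular field; 103.4° total coverage per side, matching murine visual
coverage); a `values_are_half_widths=False` switch reinterprets supplied
full-widths, because the convention of the settings is the single most
consequential free interpretation in the pipeline.

The stimulus is a 1-D segment (the screen is a wall in the top-down
view). Its sector fractions are estimated by discretising the segment
into 201 equally spaced points placed at midpoints of equal subintervals
(midpoint rule): the count/201 estimate of a sector's subtended parameter
length then errs by at most 0.5/201 per sector-boundary crossing, and no
sector has more than two crossings, so the worst error is ≤ 1.5/201 ≈
0.0075 against the exact interval oracle. On-axis samples (θ = 0) are
split evenly between `left_all`/`right_all`; a sample coinciding with the
pose origin is dropped and the fractions renormalised (logged). Sector
bounds are inclusive on the seeing side, so the blind sector is open; the
blind-frame rule itself is inclusive: a frame is **blind** when the blind
fraction ≥ 0.90, otherwise **oriented**.

## Trials, orientation index, and metrics

Each stimulus onset pairs with the next outcome event; the LH window is
[onset, outcome), half-open so the outcome instant is not double-counted.
A trial is oriented when ≥ 1 valid frame in its window is oriented;
trials with zero valid frames are *indeterminate* and leave both the
numerator and denominator of the orientation index (their count is
reported). Bins are half-open [k·900 s, (k+1)·900 s) assigned by onset —
six bins for a 90-min probe; empty bins report missing values, never 0.
Correction trials are excluded from the orientation index and from all
signal-detection rates by default (config flag to include them) and are
tallied in their own columns.

Metrics follow the standard definitions: HR = hits/(hits+misses), FAR =
FA/(FA+CR), d′ = z(HR) − z(FAR), c = −(z(HR)+z(FAR))/2, impulsivity % =
100·ITI touches / ITIs initiated (restarts count as initiations by
default; configurable), response rate = (hits+FA)/all outcomes. Extreme
rates (exactly 0 or 1) are corrected to 1/(2N) and 1 − 1/(2N) by default
(`half_count`); method `none` propagates them as missing with a warning.
Latency SDs use N−1 (reaction-time-variability convention); singleton
bins report a missing SD. The tidy long-format session report (one row
per subject–session–bin–metric) is the hand-off point to external
mixed-model software; the package deliberately fits no mixed models.

## Numerical and reproducibility choices

One global seed is fanned out through `numpy.random.SeedSequence` into
per-stage streams (all < 2³¹), so stages rerun independently yet
reproducibly; with a fixed seed the pipeline's outputs are byte-identical
across runs, and `run_all` analyses its own *persisted* files (CSV
timestamps carry µs precision) so a later `analyze` of those files agrees
byte for byte. CSV floats are re-read with round-trip precision. Event
timestamps are session-relative seconds; readers accept a configurable
offset for wall-clock exports.

Problem sizes in the test and acceptance runs are the package's own
choices: the exact ground-truth round trip runs one full 90-min session
at 30 fps (162,000 frames); the multi-seed time-on-task signature runs
TOT sessions at 10 fps, which leaves ≥ 35 frames per 3.5-s limited hold
and therefore cannot change the ≥ 1-oriented-frame statistic, while
keeping 20-replicate suites fast. The signature check itself is
statistical: the orientation-index slope's confidence interval must cover
zero while the response-rate slope's interval lies strictly below zero —
a finite set of seeds estimates the declining *expectation*; exact
monotonicity of a sample mean is not a property of the model and is not
asserted.

## Known limitations

Single animal, single camera, 2-D geometry: no 3-D head pose, eye
position or pupil tracking (all sectors are centred on the single gaze
axis — three keypoints cannot constrain more), no occlusion reasoning
beyond QC exclusion, no modelling of competing behaviours beyond the
binary orientation policy, and no inferential statistics — the pipeline
ends at tidy tables. Drug effects are representable only as agent-parameter
presets, not as pharmacokinetics.
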