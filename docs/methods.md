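# Methods

`gazeload` analyzes binocular eye-tracking recordings from a seated/standing
VR listening task for content-independent signatures of mental load, and
ships a synthetic session generator so every stage of the pipeline can be
validated end to end against known ground truth.  This note documents the
models, the defaults and their rationale, and what the synthetic validation
does and does not establish.

## Data model

A session is one participant's four listening phases (conditions
`JP-Familiar`, `JP-Unfamiliar`, `EN-Familiar`, `EN-Unfamiliar`, in increasing
intended difficulty).  Each trial is a time series of synchronized samples:
head pose (position, view and up vectors), per-eye gaze-ray origins and
directions, per-eye gaze–surface collision points, the binocular focus point
(closest approach of the two gaze rays), per-eye pupil diameters in mm with
`-1` as the closed-eye/error sentinel, and the label of the gazed object.
Coordinates are metres in a right-handed, y-up world frame; timestamps are
seconds from trial start.  Sampling is non-uniform (the recording runs at a
game engine's frame rate, nominally ~90 Hz); every pipeline stage uses the
actual timestamps.

Serialization is one wide CSV per session (fixed column schema, one row per
sample, trials concatenated) plus a YAML sidecar with participant id and the
ordered per-trial `{condition, n_samples}` list.  Optional 3D fields are
empty cells — a zero vector is legal geometry and must not collide with
"missing".

## Pupil pipeline

1. **Blink detection.** A sample is invalid when either eye reports the
   sentinel or a diameter outside 1–10 mm.  Maximal invalid runs become
   blinks, extended 200 ms before and after (at ~90 Hz the commonly used
   100 ms is too short to cover lid-closure artifacts), and merged when the
   extended spans touch.  Events carry sample indices derived from the real
   timestamps.
2. **Interpolation.** Samples inside each extended blink are replaced by
   linear interpolation between the nearest valid anchors (component-wise
   for 3D points); edge blinks are filled by constant extension.  A trial
   with no valid anchor, or no valid samples at all, is excluded as
   unusable.
3. **Smoothing.** Centered moving average per eye, default window 5 samples
   (~55 ms); the window shrinks symmetrically at the edges so constants pass
   through unchanged.
4. **Binocular combination.** Sample-wise mean where both eyes are valid,
   single-eye fallback otherwise (a strict both-eyes mode is available).
5. **Baseline correction.** Subtractive, against the mean of valid samples
   in the 0.5–2.0 s window of each trial.  A divisive variant exists behind
   a flag; subtraction is the default because the downstream statistics
   operate on mm-scale signed deviations.

Interpolated samples are flagged invalid and never enter the section
aggregates; interpolation exists so the smoothing and event chains see
continuous signals.

## Focus offset

The focus point F is where the two gaze rays come closest (closed form; the
pair is rejected as invalid when the rays are within 0.1° of parallel or
diverge, since the closest point is then numerically meaningless).  With H
the head position and S the gazed surface point (midpoint of the per-eye
collision points, or the single existing one), the focus offset is

    offset = (d_F - d_S) / d_S,   d_S = |S - H|,   d_F = (F - H) · u,

with u the unit vector from H to S.  The projection makes the sign well
defined for slightly off-axis focus points; positive means the eyes converge
behind the surface ("looking through" it), negative in front.  Dividing by
the surface distance makes the measure dimensionless and scale-invariant,
and compresses the rapidly growing vergence noise at larger distances.

Samples without a surface hit are invalid, never zero-filled.  After blink
and saccade samples are removed, each contiguous valid run is smoothed with
a Savitzky–Golay filter (window 201 samples, polynomial order 3; the window
shrinks to the largest odd length that fits short runs).  Runs are never
bridged.  Finally the smoothed offsets are centered on each participant's
median across all their trials, removing the large idiosyncratic vergence
biases that otherwise dominate between-participant comparisons.

The offset is a ratio; multiplied by a typical surface distance (~0.7 m in
the booth) it can be read in centimetres.

## Virtual screen and gaze events

Fixation/saccade classification happens in 2D: the combined gaze ray (head
position toward the focus point) is intersected with a plane 3 m ahead in
head space, expressed along the head frame's right/up axes.  The
intersection cloud is median-centered per axis and bounded by its 0.0025 and
0.9975 quantiles (one-sided per edge), which defines a per-trial virtual
screen; all points map to pixel coordinates at 150 dpi, y flipped to the
top-left screen convention.  Gaze more than 89° off the view axis is
invalid.

Classification is an adaptive velocity-threshold (I-VT) scheme: per-sample
speed in px/s from consecutive valid samples and real time steps; the
per-trial threshold is mean + 3 SD of the speeds, re-estimated on
sub-threshold speeds until convergence (max 20 iterations), with a 1 px/s
floor so that a velocity distribution that collapses to zero variance (e.g.
noise-free synthetic data) does not turn numerical jitter into saccades.
Sub-threshold runs of at least 100 ms become fixations; super-threshold runs
become saccades.  Events map back to sample indices with inward rounding —
a saccade cedes its boundary samples to the neighboring fixations — so
events never overlap; events whose motion spans three samples or fewer are
dropped as sub-resolution.  Invalid (blink) spans always break events.  A
compatibility mode replaces the per-interval durations with the trial mean
(uniform-rate assumption with end-point rescaling).

## Sectioning, aggregates, statistics

Each trial's first 40 s are split into four 10-s sections (half-open
windows; a sample at exactly 10 s belongs to section 2).  Per section the
pipeline aggregates: pupil mean and variance (valid samples only), focus
offset mean and variance, blink/fixation/saccade counts and mean durations
(an event belongs to the section containing its temporal midpoint), and the
variances of the sample-to-sample rotation angles of the head view vector
and of the averaged left/right gaze direction.  With 11 participants this
yields n = 44 aggregates per condition.

The distraction ratio divides each poster's gaze-sample count by the total
gaze-sample count on any poster, per participant and condition; it is
undefined (and the trial excluded from that analysis) when no poster was
gazed at.

The between-condition battery per metric: Shapiro–Wilk (normality of the
pooled values) and Levene (variance homogeneity) as assumption checks, a
Kruskal–Wallis omnibus across the four conditions, and — only when the
omnibus is significant at 0.05 — pairwise two-sided Wilcoxon rank-sum tests
(exact enumeration for combined n ≤ 12, normal approximation with
continuity correction otherwise) with Benjamini–Hochberg adjustment and
pooled-SD Cohen's d.  Adjacent-pair comparisons gate on Shapiro–Wilk:
normal-looking data take the (paired) t-test with a Levene report,
otherwise the Wilcoxon (signed-rank when paired); BH runs across the family
of adjacent comparisons.  Spearman's rank correlation (average ranks for
ties) is available for rating-scale analyses.

## Synthetic session generator

The generator emulates the statistical structure the pipeline assumes; it is
not a psychological model.  Condition effects are injected parameters.

**Scene.** A fixed booth: interior 1.1 m across, three walls 2.2 m high, an
open entrance, a target sphere (r = 5 cm) on the front wall at 1.5 m height
(~0.45 m from the standing eye position), and three 25 × 20 cm posters at
1.2–1.4 m height on the walls (~0.6–0.7 m away).  Ray casting over these
surfaces stands in for the engine's collision query.

**Sampling.** Instantaneous rates drawn per step from N(90.26, 5.81) Hz.

**Scanpath.** Alternating fixations and saccades.  Fixation durations are
lognormal (mean 0.31 s at baseline, log-SD 0.4, clipped to 0.15–1.5 s); per
condition the mean is divided by a fixation-rate multiplier (1.0, 0.99,
0.81, 0.93), producing the fewer-fixations-at-peak-load pattern.  Targets
are the sphere, or a random poster with a per-condition glance probability
(0.12, 0.03, 0.04, 0.08 — voluntary exploration is suppressed under load).
Saccade durations follow a main-sequence-like rule (21 ms + 2.2 ms/deg,
clipped to 60–100 ms so every saccade spans enough samples to be resolvable
at ~90 Hz); displacement follows a symmetric triangular velocity profile.
Fixational instability is angular: a slow drift (OU, 0.1°, τ = 0.3 s) plus
per-sample tracker noise (0.06°), both scaled by target distance.  A
fixation that would be cut below ~0.165 s by the trial end is not started;
the previous fixation extends instead.

**Head.** The head position sways slowly (OU, 8 mm, τ = 3 s); the view
vector low-pass tracks (τ = 1 s) a blend of straight ahead and the gaze
direction with gain 0.3 — brief eccentric glances are predominantly
eye-only, the head covering roughly a third of sustained gaze eccentricity
— plus 0.3° orientation noise.

**Onset envelope.** All load effects are multiplied by a deterministic
envelope: 0 until 2 s, cosine ramp to 1 at 5 s.  This mirrors the sluggish
task-evoked pupillary response and makes the 0.5–2 s baseline window a clean
reference.  The generator exposes envelope-weighted expected section effects
(`expected_section_pupil_shift`, …) as the ground truth that recovery tests
compare against; over the 40-s analysis window the envelope mean is 0.9125.

**Pupil.** Per participant a baseline diameter ~N(5.51, 0.93) mm clipped to
3.4–7.6 mm (the observed trial range in this paradigm spans roughly
3.25–7.74 mm).  The signal adds the enveloped condition shift (0, 0.015,
0.118, 0.030 mm — the peak value is the reported peak-condition effect;
sub-peak values are small positive shifts preserving the inverted U), an
enveloped slow OU fluctuation (0.2285 mm, τ = 3 s) and white measurement
noise (0.03 mm), both scaled by the square root of the per-condition
variance ratio (1.0, 0.95, 0.43, 0.90) so that within-section variance
scales by exactly that ratio, plus independent per-eye noise (0.02 mm).
The slow-fluctuation SD reproduces the observed within-section variance
scale (~0.030 mm² at baseline); on that scale the peak shift standardizes
to roughly one between-section SD.  The reported mm shift and the reported
SD-standardized shift cannot both be matched with one noise scale — the
published variance table and the abstract's standardization imply different
spreads — and the generator prioritizes the mm scale and the variance
table.
Because every load-coupled component shares the envelope, the injected
variance ratio holds exactly in the steady-state sections (2–4); section 1
additionally contains the deterministic onset trend, which is why recovery
estimates the ratio from sections 2–4.

**Vergence.** The logged focus point sits on the combined gaze ray at
distance d·(1 + δ), where δ is a per-participant bias N(0, 0.05) (removed
later by median centering), a slow OU component (0.03, τ = 2 s), the
enveloped condition shift (0, 0.020, 0.0729, 0.030 — the peak ratio is
5.1 cm at the ~0.70 m typical surface distance), and white noise with SD
0.05·d per metre of surface distance, so the displacement noise grows with
the square of distance, reproducing the instability of vergence for far
targets.  Per-eye gaze rays point from eye origins (±32 mm) exactly at the
focus point, so the geometric chain is self-consistent and the closest-point
computation recovers the logged focus point.

**Blinks.** Poisson-attempted at 0.12 Hz (attention-suppressed blinking),
durations ~N(0.15, 0.05) s clipped to 0.06–0.35 s.  During a blink both
pupils carry the sentinel and all gaze-derived points are dropped; for
100 ms before and after, pupil values are corrupted by a ramped dip (still
inside the valid range), which is what makes the 200 ms blink extension
necessary.  A blink is placed either fully inside one fixation (splitting
it) or fully covering one saccade (occluding the gaze shift), always leaving
at least 0.35 s of each adjacent fixation visible, so the ground truth —
expressed in the visible-evidence convention: a split fixation counts as two
epochs, an occluded saccade is removed — remains exactly recoverable by the
detector.  Placement is rejection-sampled against the scanpath; the realized
rate therefore runs some 15–25% below the attempted rate when eligible slots
are scarce, which the self-consistency tests account for.

## Validation design

* **Noise-free limit.** With all measurement noise off, a uniform rate and a
  static head, detected blink/fixation/saccade counts equal the ground truth
  exactly, and the focus offset reproduces the injected shift up to the
  sphere-curvature error across the binocular baseline (< 2·10⁻³).
* **Monte-Carlo recovery.** 50 simulated cohorts (11 participants × 4
  conditions × 45 s) run through the complete pipeline.  The cohort-level
  peak-vs-baseline contrasts of pupil mean and focus-offset mean match the
  envelope-weighted injected values within 2 Monte-Carlo SE; the
  within-section variance ratio (sections 2–4) matches the injected 0.43;
  and the inverted-U profile (peak condition has the largest pupil mean and
  the smallest fixation count) is detected in ≥ 90% of cohorts.
* **Null calibration.** On no-effect section aggregates drawn at the
  generator's section-level spread, the Kruskal–Wallis omnibus rejects at
  3–7% over 1000 replicates.  Aggregate-level draws are used here rather
  than 1000 full cohort simulations; the statistical chain under test is
  identical, and the aggregate distribution is the generator's.
* **Oracles.** The ray–ray closest point is checked against a dense
  two-parameter grid minimization (≤ 10⁻⁴ m over 500 random convergent
  pairs), Savitzky–Golay against explicit sliding-window least squares
  (≤ 10⁻⁹), the rank-sum p-value against exhaustive enumeration for
  combined n ≤ 12, and Benjamini–Hochberg against the hand-computed step-up
  rule.

**What passing does not show.** The generator injects condition effects as
clean shifts with homogeneous per-participant effect sizes, stationary noise
and a stylized scanpath; real recordings add calibration drift,
participant-specific effect heterogeneity, luminance responses, vergence
noise that is not zero-mean, task-correlated head motion, and order effects.
Recovery on synthetic cohorts validates the pipeline's correctness and
calibration, not the field effect sizes; those belong to the original
recordings.

## Numerical choices and degenerate inputs

* Unit-norm vector invariants at 10⁻⁶; round-trip serialization at 10⁻⁹
  relative (`%.12g` floats).
* Pupil validity range 1–10 mm; values outside are treated like the
  sentinel.
* The adaptive velocity threshold floors at 1 px/s; with zero velocity
  variance the whole valid span becomes a single fixation.
* Savitzky–Golay polynomial order caps at window − 1 when short segments
  force the window down; segments of < 2 samples pass through.
* A trial shorter than 40 s cannot be sectioned and is an error naming the
  shortfall; a participant without valid focus-offset data is excluded from
  centering with a warning; exclusions are collected, never silent.
* Wilcoxon rank-sum switches from exact enumeration to the continuity-
  corrected normal approximation above combined n = 12.

## Problem sizes

Default validation sizes: 50 cohorts for recovery (≈ 180k samples each),
1000 null replicates, 8 trials per event-recovery check; the acceptance
script uses 20 cohorts and 500 replicates.  These sizes put Monte-Carlo
error comfortably below the effect sizes under test.
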