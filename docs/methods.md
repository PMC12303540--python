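# Methods

This note documents the models, conventions, numerical choices and
limitations behind gaitmix.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Sensor pipeline

### Resampling and axis handling

Phone accelerometer streams are irregular (~40 Hz nominal with
jittered gaps).  All analysis runs on a uniform 100 Hz grid obtained
by linear interpolation from the first to the last timestamp — linear
rather than spline because splines invent curvature across the
occasional long gap.  The vertical axis is chosen as the channel with
the largest mean absolute value (gravity-dominant at the waist), then
de-meaned to remove gravity.  RMS, step detection and autocorrelation
all operate on this zero-mean vertical signal.

### Step detection

Butterworth low-pass (order 4, 10 Hz) applied forward-backward, then
peak picking with three constants tuned to the physiological cadence
band of 1–3 steps/s: peaks must be positive (step impulses rise above
the zero-mean baseline; without this constraint, noise bumps riding
the negative inter-step baseline are picked up), have prominence of at
least 0.3 × the filtered signal's RMS, and be separated by at least
0.25 s.  All three are exposed in `SensorConfig`.

### Regularity and symmetry

The unbiased normalized autocorrelation divides the lag-k product sum
by N−k, so coefficients are not biased toward zero at gait-relevant
lags; an O(N²) double-loop implementation serves as the oracle in the
tests.  *Ad1* is the highest autocorrelation peak in the lag window
[0.5, 1.5] × step period; the stride peak *Ad2* is searched in
(1.25, 2.75) × lag(Ad1).  The nominal stride window
[0.5, 1.5] × (2·lag(Ad1)) has the one-step peak sitting exactly on its
lower edge and the three-step peak on its upper edge; with timing
jitter the step peak always dominates the stride peak, which would pin
symmetry at 1 regardless of asymmetry, so the window is kept clear of
both neighbours.  Step regularity is Ad1 by default; whether a given
app reports Ad1, Ad2 or their mean is not standardised, so
`SensorConfig.regularity_metric` can select either alternative.
Symmetry is min/max of the two peaks, clamped to [0, 1], and defined
as 0 when either peak is non-positive.

Step variability is the CV (not the SD in seconds) of step intervals:
reported clinical values around 0.10–0.14 are consistent with a CV,
and the CV is scale-invariant across cadences.

## Video pipeline

### Conventions (stated once, used everywhere)

* Image y grows downward; geometry is computed in world coordinates
  with y flipped, so "vertical" is up.
* The horizontal reference is the direction of travel inferred from
  mid-hip displacement, making angles immune to camera roll and to
  walking direction.
* The camera-facing side is whichever side's keypoints carry higher
  mean confidence; the head landmark is the camera-side ear, with the
  nose as fallback below the confidence threshold (0.3, the common
  pose-estimation default).
* head-to-ground is the angle between the neck→ear vector and the
  travel direction.  With the ear up-and-behind the neck this sits
  near 130–140° for an upright head and *decreases* as the head
  pitches down.  head-to-body is the interior angle at the neck
  between neck→ear and neck→mid-hip.  Published values near 130° for
  both angles are reproducible under several sign conventions; the one
  chosen here is documented and absorbed by calibration, but the
  original measurement conventions cannot be independently confirmed,
  so cross-study comparisons of absolute head angles should be made
  with care.

### Frame filtering

A frame is usable when every required keypoint (camera side + nose,
neck, mid-hip) reaches the confidence threshold; this drops the
entering/leaving-the-view segments.  The longest contiguous usable run
feeds the time-series parameters and must span at least one gait
cycle at the configured cadence estimate (2 steps/s default).

### Denoising

Angle trajectories are denoised before any statistics: 3-level
Daubechies-4 decomposition with symmetric extension, detail bands
soft-thresholded at the universal threshold σ√(2 ln N) with σ the MAD
estimate from the finest detail band.  An approximation-only
reconstruction is available via `VideoConfig.denoise_mode="approx"`.
Series shorter than 16 samples (insufficient support for three db4
levels) fall back to identity with a logged warning.

### Spatiotemporal parameters

The pixel→metre scale equates mid-hip displacement over the retained
run with the walkway length (5 m default).  Heel strikes are local
maxima of horizontal ankle–ankle separation; step length is the mean
distance between consecutive alternating strike positions (for a
periodic gait this equals hip speed / cadence); step speed is step
length × cadence by definition.  Contralateral ankle *positions* are
used even when their confidence is low — sagittal pose estimators
localise the far ankle far better than they score it — and this is the
one place the far side is consulted.

## Synthetic cohort generator

### Accelerometer model

Each step deposits a Gaussian impulse on the vertical axis (σ = 15% of
the step period), on top of gravity, with white sensor noise on all
axes and a small sinusoidal sway on the horizontal axes.  Step timing
uses *lattice-anchored* jitter: independent per-step deviations around
a fixed periodic lattice, scaled so the CV of successive intervals
equals `timing_jitter_cv`.  A random-walk of intervals was rejected
because it diffuses the stride lag twice as fast as the step lag,
which makes downstream symmetry *rise* with injected asymmetry —
inverting the physical meaning of the measure.  With the lattice
model, step- and stride-lag autocorrelations see identical timing
diffusion, and the min/max symmetry responds to asymmetry alone, as
it should.  Alternate steps are scaled by (1 − asymmetry); the weak
side is fixed per recording.  The impulse width matters: for a
mean-removed pulse train the one-step autocorrelation under timing
jitter falls off as (1 + (cv·T)²/(2σ²))^(−1/2), and σ = 0.15 T is the
choice under which clinically reported variability (~0.10) and
regularity (~0.76) levels coexist.

### Keypoint walker

A sagittal stick figure: the mid-hip translates at cadence × step
length; thigh, knee, ankle, elbow and arm angles oscillate
sinusoidally at the stride frequency with configurable means and
half-ranges (legs and arms in antiphase); the trunk leans forward by a
configurable angle with ±1° sway; the neck→ear vector starts at 140°
from the travel direction for a neutral head and rotates down by
`head_pitch_offset`.  Camera-side points get confidence ≈ 0.9, the
contralateral side ≈ 0.15 (below threshold), and the first/last
`dropout_fraction` of frames have the required points zeroed with
confidence 0, emulating entry/exit dropout.  Ground-truth angle
trajectories are the analytic series; a test verifies they agree with
angles recomputed from the emitted noise-free keypoints.

Because the thigh swing is zero-mean, the extracted calf-to-vertical
mean equals the knee-angle mean — that is the knob the calibration
uses.  The walker covers 5 m / (1 − dropout) ≈ 5.6 m so that the
*retained* midsection spans the 5 m the extractor assumes.

### What the generator does not emulate

No double support or stance/swing asymmetry in time, no soft-tissue
artefact, no perspective or lens distortion, no pose-estimator
failure modes beyond confidence dropout, no correlation between
sensor and video noise.  Passing tests therefore demonstrate that the
*estimators* recover what they claim from signals with the stated
periodicity/asymmetry/posture structure — not that the generator is a
biomechanical model of CSVD gait.

## Calibration to the reference cohort

The reference is a published two-group summary (10 controls vs 19
CSVD patients; normal, dual-task and fast walking; group means and
SDs for five sensor parameters, and for calf-to-vertical,
head-to-body and head-to-ground angles).  Those printed summaries are
inputs: the generator is tuned so that the *full pipeline* reproduces
the group means, demonstrating end-to-end self-consistency of the
chain — not validity on real patients.

Per (group, task):

* cadence is set directly from the reference step frequency;
* `timing_jitter_cv` is found by a Brent root find on the mean
  pipeline regularity of a seeded 48-draw calibration cohort (the
  regularity↦jitter map is strictly decreasing; normal deviates are
  frozen across evaluations so the objective is continuous);
* `step_amplitude` starts from the closed-form pulse-train RMS and is
  refined by three multiplicative fixed-point steps against measured
  pipeline RMS on a 192-draw set (the RMS tolerance is tight relative
  to the between-participant spread, so its calibration noise budget
  is smaller);
* asymmetry per group (0.25 control, 0.35 CSVD) comes from solving
  the mean-removed pulse-train step/stride autocorrelation ratio for
  the reference symmetry means;
* head pitch = 140° − reference head-to-ground; trunk lean =
  270° − head-to-ground − head-to-body (under the stated geometry
  this reproduces both means simultaneously; the CSVD dual-task row
  implies an ~19° lean, which should be read as a calibration
  convention, not a biomechanical claim); knee-angle mean = reference
  calf-to-vertical.

Between-participant SDs use the reference SDs where a parameter maps
one-to-one (cadence, head pitch, knee angle) and a fixed 25% relative
spread for timing jitter; the reference SDs mix between-subject and
measurement variance, so only the means are claimed to be reproduced.
Task effects are additive offsets per group on top of the normal-walk
parameters, so all tasks share one generator.

The emergent step variability of the calibrated groups (~0.08
control, ~0.11 CSVD) lands close to, but is not forced to equal, the
reference values (0.10/0.12) — it is a by-product of the regularity
calibration.  Similarly, the reference RMS difference (1.64 vs 1.43,
overlapping SDs ≈ 0.45/0.42 at n = 10/19) is too small for the
simulated cohorts to flag as significant in most seeds, even though
the clinical report does; the printed SDs and the printed p-value are
not jointly reproducible under any simple two-sample model, and the
simulation follows the moments.

## Problem sizes and sampling bands

The evaluation (`gaitmix.evaluation.evaluate_targets`, used by
`scripts/acceptance.py` and the acceptance test) averages each
group-task mean over 10 replicate cohorts of 10 + 19 participants,
one repetition per task — 100–190 recordings per quantity,
30 s of accelerometry and ~5 s of 60 fps keypoints each; the whole
run, calibration included, takes tens of seconds on one CPU.  With a
between-participant head-pitch SD of 8.28° (the reference SD), the
grand mean over 100 draws has a standard error of ≈ 0.8°, so a ±2°
check on a head angle sits at ≈ 2.4σ and can fail for an unlucky
seed (~2% of seeds per angle); the regularity and RMS checks sit at
≈ 3σ.  These bands are inherent to the prescribed cohort size, not to
estimator error, and were left as is.

The null-calibration test runs 20 replicate 8-vs-8 cohorts with
identical group distributions, 2 tasks × 5 parameters each (200
p-values); the acceptance band (0–11%) is a 3σ binomial band around
5% that also admits the conservatism of the discrete exact test.

## Known limitations

* The head/calf angle conventions are calibrated, not confirmed;
  absolute values are comparable within this package only.
* The sensor RMS depends on the vertical-axis convention (per-axis,
  not resultant magnitude); the calibration absorbs the scale.
* Exact Mann-Whitney p-values are used only for min(n₁, n₂) ≤ 8 and
  no ties; at the study's 10-vs-19 size the tie-corrected normal
  approximation with continuity correction is used, which is standard
  but approximate.
* The pixel scale assumes the retained run spans the stated walkway
  length; datasets where the walker is tracked over a different
  distance need `walkway_length` set accordingly.
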