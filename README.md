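# gaitmix

Two-channel gait assessment for studies of cerebral small vessel
disease (CSVD) and similar neurological gait disorders: smartphone
accelerometry for temporal gait dynamics, markerless video pose
estimation for posture, and the group statistics that tie them
together — plus a synthetic cohort generator with known ground truth,
so the whole chain is testable without any participant data.

## Who this is for

Researchers building or validating low-cost gait biomarkers.  CSVD
impairs gait before it impairs cognition; the signature reported in
clinical work is reduced *step regularity*, reduced vertical
acceleration *RMS*, and a *forward head posture* (smaller head-to-body
and head-to-ground angles).  Neither a waist-worn phone nor a side-view
camera alone captures all of these; the package implements both
channels behind one feature table.

## What it computes

**Sensor channel** (tri-axial waist accelerometer, ~40 Hz, 30 s walks):
the recording is resampled to 100 Hz by linear interpolation, the
gravity-dominant axis is selected and de-meaned, and five parameters
are extracted:

* step frequency *f* — reciprocal mean step interval from peak detection;
* acceleration RMS — intensity of the vertical dynamic acceleration;
* step variability — CV of step intervals, SD(Δt)/mean(Δt);
* step regularity *Ad1* — the unbiased autocorrelation coefficient
  at the one-step lag: ρ(k) = [Σᵢ xᵢxᵢ₊ₖ / (N−k)] / ρ(0), peak in the
  window [0.5, 1.5]·(1/f);
* step symmetry — min(Ad1, Ad2)/max(Ad1, Ad2), with *Ad2* the
  one-stride-lag peak; 1 means left and right steps are
  indistinguishable.

**Video channel** (BODY_25 keypoints from side-view 1080p/60 fps
video, one JSON per frame): frames with incomplete detections (walker
entering/leaving the view) are filtered out, joint-angle trajectories
are computed on the camera-facing side, denoised with a 3-level
Daubechies-4 wavelet transform (soft universal threshold), and
summarised: mean + variance for the five gait-cycling joint angles
(knee, ankle, elbow, upper-arm–trunk, trunk–thigh), mean for six
postural angles (neck–trunk, body lean, sight line, head-to-body,
head-to-ground, calf-to-vertical), plus heel height, step length and
step speed via the walkway-length pixel scale.

**Statistics**: per-task Mann-Whitney U comparisons (exact by
enumeration for small samples, tie-corrected normal approximation
otherwise), Welch-t/chi-square demographics, and headline effect
summaries (relative regularity deficit, head-angle gaps).

**Synthetic cohort**: a Gaussian-impulse accelerometer model and a
sagittal stick-figure keypoint walker, with controllable cadence,
intensity, timing jitter, left/right asymmetry, head pitch and
keypoint dropout.  `gaitmix.calibration.calibrated_design()` tunes the
generator so the *pipeline output* reproduces the reference group
means of a 10-control / 19-CSVD clinical cohort across normal, dual-task
and fast walking.

## Worked example

Simulate the calibrated two-group cohort, extract both feature sets,
and compare groups:

```python
from gaitmix import calibrated_design, simulate_cohort, compare_groups, headline_effects
from gaitmix.pipeline import extract_cohort_features

design = calibrated_design(tasks=("normal", "dual"), repetitions=1, seed=7)
cohort = simulate_cohort(design)              # 29 participants x 2 tasks
feats = extract_cohort_features(cohort).features
comp = compare_groups(feats, parameters=["step_regularity", "rms", "head_to_ground_mean"])
print(comp[["task", "parameter", "control_mean", "csvd_mean", "u_statistic", "p_value"]])
print(headline_effects(comp))
```

Output (one seeded cohort; group means carry n=10/19 sampling noise):

```
  task           parameter  control_mean  csvd_mean  u_statistic  p_value
normal     step_regularity         0.775      0.557          9.0    0.000
normal                 rms         1.467      1.387         85.0    0.663
normal head_to_ground_mean       135.826    129.302         42.0    0.016
  dual     step_regularity         0.790      0.495          0.0    0.000
  dual                 rms         1.449      1.218         51.0    0.046
  dual head_to_ground_mean       136.030    125.838         27.0    0.002

  task  regularity_rel_diff_pct  head_to_ground_gap_deg
normal                    28.11                    6.52
  dual                    37.38                   10.19
```

The CSVD-like group walks with markedly lower step regularity and a
head pitched several degrees further down — the pattern the pipeline
is designed to detect.  The U statistic is `min(U, n₁n₂ − U)`; p-values
are two-sided and unadjusted (a Benjamini-Hochberg column is emitted
as supplementary output).

A command-line surface wraps the same steps for on-disk datasets
(accelerometer CSVs and per-frame keypoint JSON in the standard pose
estimator dialect, so real OpenPose output drops in unchanged):

```bash
gaitmix simulate --out data/ --seed 1
gaitmix extract  --in data/ --out features.csv
gaitmix compare  --features features.csv --out report/
```

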