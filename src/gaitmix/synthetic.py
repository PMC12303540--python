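"""Synthetic gait cohort generator.

Generates the two raw data streams the analysis pipelines consume --
waist-accelerometer recordings and sagittal BODY_25 keypoint sequences
-- with known ground truth, at single-recording and cohort scale.

The accelerometer model is deliberately phenomenological: each heel
strike deposits a Gaussian-shaped vertical acceleration impulse (width
15% of the step period), with per-step timing and amplitude jitter,
alternate steps scaled down by the asymmetry factor (the weak side is
fixed per participant), gravity on the vertical axis, and white sensor
noise on all axes.  The downstream sensor pipeline only consumes
periodicity, amplitude and left/right structure, so a biomechanical
model would add nothing testable.

The keypoint walker is a sagittal-plane stick figure: the mid-hip
translates at cadence x step length, the limb segments oscillate
sinusoidally over the gait cycle with configurable means and
half-ranges, the head (neck-to-ear vector) is pitched by a
configurable offset, and coordinates are converted to pixels.  The
camera-facing side carries high keypoint confidence and the
contralateral side low confidence, matching side-view capture; the
first/last fraction of frames emulate the walker entering/leaving the
field of view by zeroing the required points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from . import body25
from .errors import DegenerateInputError, ParameterError
from .types import AccelerometerRecording, KeypointSequence

GRAVITY = 9.81  # m/s^2

#: Gaussian impulse width (one sigma) as a fraction of the step period;
#: at 0.15 the reference step-variability and step-regularity levels are
#: jointly attainable (narrower pulses make the one-step autocorrelation
#: implausibly sensitive to timing jitter)
PULSE_WIDTH_FRAC = 0.15

#: neck->ear direction for a neutral (un-pitched) head, degrees from the
#: forward horizontal; the ear sits up-and-behind the neck, so pitching the
#: head down rotates this vector toward the travel direction.
HEAD_NEUTRAL_DEG = 140.0


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class GaitSimParams:
    """Ground-truth parameters for one accelerometer recording."""

    step_frequency: float = 1.75  # steps/s
    step_amplitude: float = 4.5  # m/s^2 vertical peak per step
    timing_jitter_cv: float = 0.08  # CV of step intervals
    amplitude_jitter_cv: float = 0.10  # CV of per-step amplitude
    asymmetry: float = 0.10  # weak-side amplitude scaled by (1 - asymmetry)
    noise_sd: float = 0.25  # m/s^2 white sensor noise
    duration: float = 30.0  # s
    nominal_rate: float = 40.0  # Hz
    rate_jitter_cv: float = 0.10  # CV of inter-sample gaps
    seed: int = 0

    def validate(self) -> None:
        if self.step_frequency <= 0:
            raise ParameterError("step_frequency must be positive")
        if min(self.timing_jitter_cv, self.amplitude_jitter_cv, self.rate_jitter_cv) < 0:
            raise ParameterError("jitter CVs must be non-negative")
        if not 0 <= self.asymmetry < 1:
            raise ParameterError("asymmetry must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if self.duration <= 0:
            raise ParameterError("duration must be positive")
        if self.nominal_rate <= 0:
            raise ParameterError("nominal_rate must be positive")
        if self.step_amplitude <= 0:
            raise ParameterError("step_amplitude must be positive")


@dataclass(frozen=True)
class PostureSimParams:
    """Ground-truth parameters for one keypoint sequence."""

    cadence: float = 1.75  # steps/s
    step_length: float = 0.55  # m; hip speed = cadence * step_length
    knee_mean: float = 160.0  # deg, interior hip-knee-ankle angle
    knee_half: float = 5.0  # deg half-range
    ankle_mean: float = 105.0
    ankle_half: float = 8.0
    elbow_mean: float = 155.0
    elbow_half: float = 8.0
    thigh_swing_half: float = 9.0  # deg, thigh from vertical
    arm_swing_half: float = 10.0  # deg, upper arm from vertical
    head_pitch_offset: float = 6.0  # deg of downward head pitch from neutral
    head_bob_half: float = 1.0  # deg oscillation of the head pitch
    trunk_lean: float = 3.0  # deg forward of vertical
    trunk_sway_half: float = 1.0  # deg oscillation of the lean
    walk_distance: float = 5.0  # m
    fps: float = 60.0
    image_scale: float = 300.0  # px / m
    image_height: float = 1080.0  # px
    keypoint_noise_sd: float = 2.0  # px
    dropout_fraction: float = 0.10  # edge frames with missing detections
    seed: int = 0

    def validate(self) -> None:
        if self.fps <= 0:
            raise ParameterError("fps must be positive")
        if self.image_scale <= 0:
            raise ParameterError("image_scale must be positive")
        if not 0 <= self.dropout_fraction <= 1:
            raise ParameterError("dropout_fraction must lie in [0, 1]")
        for name in ("knee_half", "ankle_half", "elbow_half", "thigh_swing_half",
                     "arm_swing_half", "head_bob_half", "trunk_sway_half"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.walk_distance <= 0:
            raise ParameterError("walk_distance must be positive")
        if self.cadence <= 0 or self.step_length <= 0:
            raise ParameterError("cadence and step_length must be positive")
        if self.keypoint_noise_sd < 0:
            raise ParameterError("keypoint_noise_sd must be non-negative")


# ---------------------------------------------------------------------------
# accelerometer simulation


@dataclass(frozen=True)
class SimulatedRecording:
    """An accelerometer recording with its generating ground truth."""

    recording: AccelerometerRecording
    step_times: np.ndarray
    step_amplitudes: np.ndarray
    vertical_axis: str
    weak_side_parity: int  # steps with index % 2 == parity are the weak side
    params: GaitSimParams

    @property
    def step_count(self) -> int:
        return int(self.step_times.size)


def simulate_accelerometer(params: GaitSimParams) -> SimulatedRecording:
    """Simulate one waist-accelerometer recording.

    The vertical axis (labelled ``az``) carries gravity plus a
    step-periodic train of Gaussian impulses; the horizontal axes carry
    a small mediolateral sway and noise.  Sample timestamps are
    irregular with the configured mean rate and gap CV.  Ground truth
    (step times and per-step amplitudes) is returned alongside.
    """
    params.validate()
    period = 1.0 / params.step_frequency
    if params.duration < 3 * period:
        raise DegenerateInputError("duration must cover at least 3 step periods")
    rng = np.random.default_rng(params.seed)

    # irregular sample grid
    mean_gap = 1.0 / params.nominal_rate
    n_est = int(params.duration / mean_gap * 1.5) + 16
    gaps = mean_gap * np.maximum(1.0 + params.rate_jitter_cv * rng.standard_normal(n_est), 0.2)
    ts = np.concatenate([[0.0], np.cumsum(gaps)])
    ts = ts[ts <= params.duration]

    # step train: independent per-step deviations around a fixed lattice,
    # so the phase does not random-walk over the bout (step- and stride-lag
    # autocorrelations then see the same timing diffusion).  The deviation
    # SD is cv * period / sqrt(2) so the CV of successive intervals equals
    # the stated timing_jitter_cv.
    n_steps = int(math.floor((params.duration - 0.5 * period) / period)) + 1
    lattice = 0.5 * period + np.arange(n_steps) * period
    dev = (params.timing_jitter_cv * period / math.sqrt(2.0)) * rng.standard_normal(n_steps)
    step_times = np.sort(np.clip(lattice + dev, 0.0, params.duration))
    amps = params.step_amplitude * np.maximum(
        1.0 + params.amplitude_jitter_cv * rng.standard_normal(step_times.size), 0.1
    )
    parity = int(rng.integers(2))
    amps[parity::2] *= 1.0 - params.asymmetry

    sigma = PULSE_WIDTH_FRAC * period
    # (n_samples, n_steps) outer difference; recordings are short enough
    # that the dense product is cheap
    dt = ts[:, None] - step_times[None, :]
    vert = (np.exp(-0.5 * (dt / sigma) ** 2) * amps[None, :]).sum(axis=1)

    t_arr = 2 * np.pi * params.step_frequency * ts
    ax = 0.15 * params.step_amplitude * np.sin(0.5 * t_arr)  # mediolateral sway
    ay = 0.10 * params.step_amplitude * np.sin(t_arr + 0.8)  # anteroposterior
    noise = params.noise_sd * rng.standard_normal((ts.size, 3))
    acc = np.column_stack([ax, ay, GRAVITY + vert]) + noise

    rec = AccelerometerRecording(
        timestamps=ts, acceleration=acc, axis_labels=("ax", "ay", "az")
    )
    return SimulatedRecording(
        recording=rec,
        step_times=step_times,
        step_amplitudes=amps,
        vertical_axis="az",
        weak_side_parity=parity,
        params=params,
    )


# ---------------------------------------------------------------------------
# keypoint simulation


def _rot(v: np.ndarray, deg: np.ndarray | float) -> np.ndarray:
    """Rotate 2D vectors counterclockwise by ``deg`` degrees (vectorized)."""
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    x, y = v[..., 0], v[..., 1]
    return np.stack([c * x - s * y, s * x + c * y], axis=-1)


def _unit(deg: np.ndarray | float) -> np.ndarray:
    a = np.radians(deg)
    return np.stack([np.cos(a), np.sin(a)], axis=-1)


# segment lengths of the stick figure, metres
_L_TRUNK = 0.55
_L_THIGH = 0.42
_L_CALF = 0.42
_L_FOOT = 0.22
_L_HEEL = 0.07
_L_UPPER_ARM = 0.30
_L_FOREARM = 0.26
_L_EAR = 0.15
_L_NOSE = 0.18
_HIP_HEIGHT = 0.95
_HIP_BOB = 0.012  # m vertical hip oscillation at step frequency


@dataclass(frozen=True)
class SimulatedKeypoints:
    """A keypoint sequence with its generating ground truth.

    ``truth`` maps angle names to the analytic per-frame trajectories
    (degrees, over *all* frames, before pixel noise and dropout); the
    scalar entries record the spatiotemporal truth.
    """

    sequence: KeypointSequence
    truth: dict[str, np.ndarray]
    step_length_m: float
    cadence: float
    speed_mps: float
    scale_px_per_m: float
    dropout_frames: tuple[int, int]  # leading, trailing
    params: PostureSimParams


def simulate_keypoints(params: PostureSimParams) -> SimulatedKeypoints:
    """Simulate a sagittal stick-figure walker as a keypoint sequence.

    The walker translates toward +x at ``cadence * step_length`` m/s
    over ``walk_distance`` metres.  Right-side joints face the camera
    (high confidence); left-side joints get low confidence, matching
    side-view capture.  The analytic angle trajectories are returned as
    ground truth.
    """
    params.validate()
    speed = params.cadence * params.step_length
    duration = params.walk_distance / speed
    n = int(math.floor(duration * params.fps)) + 1
    t = np.arange(n) / params.fps
    stride_f = params.cadence / 2.0
    phase = 2 * np.pi * stride_f * t
    rng = np.random.default_rng(params.seed)

    pos = np.zeros((n, body25.N_KEYPOINTS, 2))  # world metres, y up

    midhip = np.stack(
        [0.3 + speed * t, _HIP_HEIGHT + _HIP_BOB * np.cos(2 * phase)], axis=-1
    )
    lean = params.trunk_lean + params.trunk_sway_half * np.sin(phase)
    trunk_dir = np.stack([np.sin(np.radians(lean)), np.cos(np.radians(lean))], axis=-1)
    neck = midhip + _L_TRUNK * trunk_dir

    theta_head = HEAD_NEUTRAL_DEG - params.head_pitch_offset + (
        params.head_bob_half * np.sin(phase + 0.7)
    )
    ear = neck + _L_EAR * _unit(theta_head)
    nose = neck + _L_NOSE * _unit(theta_head - 55.0)
    eye = neck + 0.17 * _unit(theta_head - 35.0)

    shoulder = neck - 0.05 * trunk_dir

    truth: dict[str, np.ndarray] = {}
    for side, ph0 in (("right", 0.0), ("left", np.pi)):
        jj = body25.SIDE_JOINTS[side]
        s = np.sin(phase + ph0)
        q = np.sin(phase + ph0 + np.pi / 2)

        thigh_deg = params.thigh_swing_half * s  # from down-vertical, + forward
        knee_int = params.knee_mean + params.knee_half * q
        calf_deg = thigh_deg - (180.0 - knee_int)  # signed, from down-vertical
        ankle_int = params.ankle_mean + params.ankle_half * q

        thigh_dir = np.stack(
            [np.sin(np.radians(thigh_deg)), -np.cos(np.radians(thigh_deg))], axis=-1
        )
        calf_dir = np.stack(
            [np.sin(np.radians(calf_deg)), -np.cos(np.radians(calf_deg))], axis=-1
        )
        hip = midhip  # sagittal projection: hip joints coincide with mid-hip
        knee = hip + _L_THIGH * thigh_dir
        ankle = knee + _L_CALF * calf_dir
        toe = ankle + _L_FOOT * _rot(-calf_dir, -ankle_int)
        heel = ankle + _L_HEEL * _rot(-calf_dir, 150.0)

        arm_deg = params.arm_swing_half * np.sin(phase + ph0 + np.pi)
        upper_dir = np.stack(
            [np.sin(np.radians(arm_deg)), -np.cos(np.radians(arm_deg))], axis=-1
        )
        elbow_int = params.elbow_mean + params.elbow_half * np.sin(phase + ph0 + np.pi / 2)
        elbow = shoulder + _L_UPPER_ARM * upper_dir
        wrist = elbow + _L_FOREARM * _rot(upper_dir, 180.0 - elbow_int)

        pos[:, jj["hip"]] = hip
        pos[:, jj["knee"]] = knee
        pos[:, jj["ankle"]] = ankle
        pos[:, jj["big_toe"]] = toe
        pos[:, jj["small_toe"]] = toe - np.array([0.03, 0.0])
        pos[:, jj["heel"]] = heel
        pos[:, jj["shoulder"]] = shoulder
        pos[:, jj["elbow"]] = elbow
        pos[:, jj["wrist"]] = wrist
        pos[:, jj["ear"]] = ear
        pos[:, jj["eye"]] = eye

        if side == "right":  # camera-facing side: record the analytic truth
            truth["knee"] = knee_int
            truth["ankle"] = ankle_int
            truth["elbow"] = elbow_int
            truth["calf_to_vertical"] = 180.0 - np.abs(calf_deg)
            truth["head_to_ground"] = theta_head
            truth["head_to_body"] = (270.0 - lean) - theta_head
            truth["body_lean"] = np.abs(lean)

    pos[:, body25.NOSE] = nose
    pos[:, body25.NECK] = neck
    pos[:, body25.MID_HIP] = midhip

    # world -> pixels (image y grows downward)
    px = pos * params.image_scale
    px[:, :, 1] = params.image_height - px[:, :, 1]
    px += params.keypoint_noise_sd * rng.standard_normal(px.shape)

    conf = np.zeros((n, body25.N_KEYPOINTS))
    right_idx = [v for v in body25.SIDE_JOINTS["right"].values()]
    left_idx = [v for v in body25.SIDE_JOINTS["left"].values()]
    central = list(body25.CENTRAL_POINTS)
    conf[:, right_idx + central] = np.clip(
        0.92 + 0.03 * rng.standard_normal((n, len(right_idx) + len(central))), 0.5, 1.0
    )
    conf[:, left_idx] = np.clip(
        0.15 + 0.03 * rng.standard_normal((n, len(left_idx))), 0.01, 0.29
    )

    n_drop = int(round(params.dropout_fraction * n))
    lead, trail = n_drop // 2, n_drop - n_drop // 2
    req = list(body25.required_points("right"))
    for sl in (slice(0, lead), slice(n - trail, n) if trail else slice(0, 0)):
        px[sl][:, req] = 0.0
        conf[sl][:, req] = 0.0

    seq = KeypointSequence(
        fps=params.fps, points=px, confidence=conf, image_height=params.image_height
    )
    return SimulatedKeypoints(
        sequence=seq,
        truth=truth,
        step_length_m=params.step_length,
        cadence=params.cadence,
        speed_mps=speed,
        scale_px_per_m=params.image_scale,
        dropout_frames=(lead, trail),
        params=params,
    )


# ---------------------------------------------------------------------------
# cohort simulation


#: physiological clipping bounds applied to per-participant draws
FIELD_BOUNDS = {
    "step_frequency": (0.8, 3.5),
    "step_amplitude": (0.3, 12.0),
    "timing_jitter_cv": (0.004, 0.5),
    "amplitude_jitter_cv": (0.0, 0.6),
    "asymmetry": (0.0, 0.8),
    "cadence": (0.8, 3.5),
    "step_length": (0.25, 1.0),
    "knee_mean": (140.0, 176.0),
    "head_pitch_offset": (-30.0, 60.0),
    "trunk_lean": (-5.0, 45.0),
}


def _clip_field(name: str, value: float) -> float:
    lo, hi = FIELD_BOUNDS.get(name, (-np.inf, np.inf))
    return float(np.clip(value, lo, hi))


@dataclass(frozen=True)
class TaskOffsets:
    """Additive per-task parameter offsets, so tasks reuse one generator.

    A task entry in :class:`CohortDesign` may be a single
    ``TaskOffsets`` (applied to both groups) or a ``{group: TaskOffsets}``
    mapping when the task effect differs between groups.
    """

    gait: dict[str, float] = field(default_factory=dict)
    posture: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class GroupSpec:
    """Parameter distributions (mean + SD per field) for one group."""

    gait: GaitSimParams
    posture: PostureSimParams
    gait_sd: dict[str, float] = field(default_factory=dict)
    posture_sd: dict[str, float] = field(default_factory=dict)
    demographics: dict[str, tuple[float, float]] = field(default_factory=dict)
    male_fraction: float = 0.5


@dataclass(frozen=True)
class CohortDesign:
    """A two-group, multi-task, repeated-measures cohort layout."""

    n_control: int
    n_csvd: int
    control: GroupSpec
    csvd: GroupSpec
    tasks: dict[str, TaskOffsets] = field(
        default_factory=lambda: {"normal": TaskOffsets()}
    )
    repetitions: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_control < 1 or self.n_csvd < 1:
            raise ParameterError("each group needs at least 1 participant")
        if self.repetitions < 1:
            raise ParameterError("repetitions must be >= 1")
        for spec in (self.control, self.csvd):
            if any(sd < 0 for sd in spec.gait_sd.values()):
                raise ParameterError("gait SDs must be non-negative")
            if any(sd < 0 for sd in spec.posture_sd.values()):
                raise ParameterError("posture SDs must be non-negative")


@dataclass(frozen=True)
class CohortRecord:
    """One (participant, task, repetition) cell of the cohort."""

    participant: str
    group: str
    task: str
    repetition: int
    accel: SimulatedRecording
    video: SimulatedKeypoints


@dataclass
class CohortData:
    records: list[CohortRecord]
    metadata: pd.DataFrame
    design: CohortDesign


def _draw_params(base, sd: dict[str, float], rng: np.random.Generator):
    drawn = {}
    for name in sorted(sd):
        mean = getattr(base, name)
        drawn[name] = _clip_field(name, mean + sd[name] * rng.standard_normal())
    return replace(base, **drawn)


def _apply_offsets(base, offsets: dict[str, float]):
    if not offsets:
        return base
    updates = {
        name: _clip_field(name, getattr(base, name) + delta)
        for name, delta in offsets.items()
    }
    return replace(base, **updates)


def simulate_cohort(design: CohortDesign) -> CohortData:
    """Simulate a full cohort: recordings + keypoints + metadata.

    For each participant, individual parameters are drawn once from the
    group distributions; task offsets are applied additively on top;
    each repetition gets a fresh recording seed.  Fully reproducible
    from ``design.seed``.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    records: list[CohortRecord] = []
    rows: list[dict] = []
    for group, spec, n, prefix in (
        ("control", design.control, design.n_control, "C"),
        ("csvd", design.csvd, design.n_csvd, "P"),
    ):
        for i in range(n):
            pid = f"{prefix}{i + 1:02d}"
            demo = {
                k: float(np.clip(m + s * rng.standard_normal(), 1e-6, None))
                for k, (m, s) in sorted(spec.demographics.items())
            }
            sex = "M" if rng.random() < spec.male_fraction else "F"
            gait_p = _draw_params(spec.gait, spec.gait_sd, rng)
            post_p = _draw_params(spec.posture, spec.posture_sd, rng)
            for task, entry in design.tasks.items():
                offsets = entry if isinstance(entry, TaskOffsets) else entry[group]
                gait_t = _apply_offsets(gait_p, offsets.gait)
                post_t = _apply_offsets(post_p, offsets.posture)
                for rep in range(1, design.repetitions + 1):
                    seed_a = int(rng.integers(2**31 - 1))
                    seed_v = int(rng.integers(2**31 - 1))
                    accel = simulate_accelerometer(replace(gait_t, seed=seed_a))
                    video = simulate_keypoints(replace(post_t, seed=seed_v))
                    records.append(
                        CohortRecord(pid, group, task, rep, accel, video)
                    )
                    row = {
                        "participant": pid,
                        "group": group,
                        "task": task,
                        "repetition": rep,
                        "sex": sex,
                        **{f"{k}": v for k, v in demo.items()},
                        "gt_step_frequency": gait_t.step_frequency,
                        "gt_step_amplitude": gait_t.step_amplitude,
                        "gt_timing_jitter_cv": gait_t.timing_jitter_cv,
                        "gt_asymmetry": gait_t.asymmetry,
                        "gt_cadence": post_t.cadence,
                        "gt_step_length": post_t.step_length,
                        "gt_head_pitch_offset": post_t.head_pitch_offset,
                        "gt_knee_mean": post_t.knee_mean,
                    }
                    if "height_cm" in demo and "weight_kg" in demo:
                        row["bmi"] = demo["weight_kg"] / (demo["height_cm"] / 100.0) ** 2
                    rows.append(row)
    return CohortData(records=records, metadata=pd.DataFrame(rows), design=design)
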