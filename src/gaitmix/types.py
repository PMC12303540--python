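"""Core domain containers shared across the sensor and video pipelines."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .errors import DegenerateInputError, FormatError, ParameterError


@dataclass
class AccelerometerRecording:
    """Timestamped tri-axial acceleration from a waist-worn smartphone.

    Timestamps are seconds, strictly increasing but irregular (the
    phone samples at roughly 40 Hz with jittered gaps).  Acceleration
    is in m/s^2, one column per device axis.
    """

    timestamps: np.ndarray
    acceleration: np.ndarray  # shape (n, 3)
    axis_labels: tuple[str, str, str] = ("ax", "ay", "az")
    placement: str = "L3 waist"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.acceleration = np.asarray(self.acceleration, dtype=float)
        if self.timestamps.ndim != 1 or self.timestamps.size < 2:
            raise DegenerateInputError("recording needs at least 2 samples")
        if self.acceleration.shape != (self.timestamps.size, 3):
            raise FormatError(
                f"acceleration shape {self.acceleration.shape} does not match "
                f"{self.timestamps.size} timestamps x 3 axes"
            )
        if np.any(np.diff(self.timestamps) <= 0):
            raise FormatError("timestamps must be strictly increasing")

    @property
    def span(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class UniformSignal:
    """A single channel resampled onto a uniform time grid."""

    rate: float
    samples: np.ndarray
    origin: float = 0.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ParameterError("rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise FormatError("samples must be finite")

    @property
    def span(self) -> float:
        return (self.samples.size - 1) / self.rate if self.samples.size else 0.0

    def times(self) -> np.ndarray:
        return self.origin + np.arange(self.samples.size) / self.rate


@dataclass(frozen=True)
class GaitFeatures:
    """The five accelerometer-derived gait parameters for one recording."""

    step_frequency: float  # steps / second
    rms: float  # m/s^2, zero-mean vertical acceleration
    step_variability: float  # CV of step intervals, unitless
    step_regularity: float  # one-step-lag autocorrelation, in [-1, 1]
    step_symmetry: float  # min/max of step- and stride-lag peaks, in [0, 1]

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class SensorQC:
    """Per-recording quality-control record from the sensor pipeline."""

    step_count: int
    vertical_axis: str
    ad1_lag_s: float
    ad2_lag_s: float
    resample_rate: float


@dataclass
class KeypointSequence:
    """Per-frame 25-point 2D skeleton with confidences, at a fixed fps.

    Coordinates are image pixels (y grows downward); confidences lie in
    [0, 1] with 0 meaning the point was not detected.
    """

    fps: float
    points: np.ndarray  # (n_frames, 25, 2) pixels
    confidence: np.ndarray  # (n_frames, 25)
    image_height: float = 1080.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ParameterError("fps must be positive")
        self.points = np.asarray(self.points, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.points.ndim != 3 or self.points.shape[1:] != (25, 2):
            raise FormatError("points must have shape (n_frames, 25, 2)")
        if self.confidence.shape != self.points.shape[:2]:
            raise FormatError("confidence must have shape (n_frames, 25)")
        if np.any((self.confidence < 0) | (self.confidence > 1)):
            raise FormatError("confidences must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    def subset(self, indices: np.ndarray) -> "KeypointSequence":
        return KeypointSequence(
            fps=self.fps,
            points=self.points[indices],
            confidence=self.confidence[indices],
            image_height=self.image_height,
        )


@dataclass
class AngleSeries:
    """One named angle trajectory over the retained video frames."""

    name: str
    values: np.ndarray  # degrees
    frame_indices: np.ndarray  # provenance into the original sequence

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        if not np.all(np.isfinite(self.values)):
            raise FormatError(f"angle series '{self.name}' contains non-finite values")


@dataclass(frozen=True)
class PostureFeatures:
    """Video-derived postural and spatiotemporal parameters for one clip.

    The five joint angles that oscillate with the gait cycle carry a
    mean and a variance; the six postural angles carry means only.
    Lengths are metres, recovered through the walkway-length scale.
    """

    knee_mean: float
    knee_var: float
    ankle_mean: float
    ankle_var: float
    elbow_mean: float
    elbow_var: float
    upper_arm_trunk_mean: float
    upper_arm_trunk_var: float
    trunk_thigh_mean: float
    trunk_thigh_var: float
    neck_trunk_mean: float
    body_lean_mean: float
    sight_line_mean: float
    head_to_body_mean: float
    head_to_ground_mean: float
    calf_to_vertical_mean: float
    heel_height_m: float
    step_length_m: float
    step_speed_mps: float
    cadence_steps_per_s: float
    retained_frame_fraction: float
    side: str = "right"

    def as_dict(self) -> dict[str, float]:
        d = {}
        for f in fields(self):
            if f.name == "side":
                continue
            d[f.name] = getattr(self, f.name)
        return d
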