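"""Video-keypoint postural and spatiotemporal gait parameters.

Consumes per-frame BODY_25 keypoint sequences (as produced by
markerless pose estimation on a sagittal walking video, 60 fps) and
extracts joint-angle trajectories plus spatiotemporal parameters.

Conventions, stated once and used everywhere:

* The image y-axis points down; all geometry is computed in *world*
  coordinates obtained by flipping y (``y_w = image_height - y_px``),
  so "vertical" means up.
* The horizontal reference is the direction of travel, inferred from
  the mid-hip displacement over the clip, so camera roll or walking
  direction do not bias the angles.
* The head landmark is the camera-side ear, falling back to the nose
  when the ear repeatedly fails the confidence filter.
* The camera-facing side is the side whose required keypoints carry
  the higher mean confidence over the clip.

Angle trajectories are denoised with a 3-level Daubechies-4 wavelet
decomposition (soft universal threshold on the detail bands) before
any summary statistics are taken.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pywt
from scipy.signal import find_peaks

from . import body25
from .errors import (
    DegenerateGeometryError,
    FormatError,
    GaitmixError,
    InsufficientFramesError,
    InsufficientStepsError,
    ParameterError,
    StageError,
)
from .types import AngleSeries, KeypointSequence, PostureFeatures

log = logging.getLogger(__name__)

#: the five joint angles that oscillate with the gait cycle (mean + variance)
DYNAMIC_ANGLES = ("knee", "ankle", "elbow", "upper_arm_trunk", "trunk_thigh")
#: the six postural angles summarised by their mean only
POSTURAL_ANGLES = (
    "neck_trunk",
    "body_lean",
    "sight_line",
    "head_to_body",
    "head_to_ground",
    "calf_to_vertical",
)


@dataclass(frozen=True)
class VideoConfig:
    """Extraction constants for the video pipeline."""

    conf_threshold: float = 0.3  # community-default keypoint confidence cutoff
    cadence_estimate: float = 2.0  # steps/s, sets the minimum usable run length
    wavelet: str = "db4"
    wavelet_level: int = 3
    denoise_mode: str = "soft"  # "soft" (thresholded details) or "approx"
    walkway_length: float = 5.0  # metres covered by the analysed run


DEFAULT_VIDEO_CONFIG = VideoConfig()


# ---------------------------------------------------------------------------
# parsing


def parse_openpose_json(
    frame_files: Iterable[str | Path],
    fps: float = 60.0,
    image_height: float = 1080.0,
) -> KeypointSequence:
    """Read one-JSON-per-frame keypoint output into a sequence.

    Files are ordered by filename (pose estimators zero-pad the frame
    index, so lexicographic order is frame order).  A frame whose
    ``people`` array is empty becomes an all-zero-confidence frame;
    when several people are present the one spanning the largest
    bounding box is kept.
    """
    paths = sorted(Path(p) for p in frame_files)
    if not paths:
        raise FormatError("no keypoint files given")
    pts = np.zeros((len(paths), body25.N_KEYPOINTS, 2))
    conf = np.zeros((len(paths), body25.N_KEYPOINTS))
    for i, path in enumerate(paths):
        try:
            with open(path) as fh:
                doc = json.load(fh)
        except (OSError, json.JSONDecodeError) as exc:
            raise FormatError(f"{path}: {exc}") from exc
        people = doc.get("people", [])
        best, best_area = None, -1.0
        for person in people:
            flat = person.get("pose_keypoints_2d", [])
            if len(flat) != 3 * body25.N_KEYPOINTS:
                raise FormatError(
                    f"{path}: expected {3 * body25.N_KEYPOINTS} values per person, "
                    f"got {len(flat)}"
                )
            arr = np.asarray(flat, dtype=float).reshape(body25.N_KEYPOINTS, 3)
            valid = arr[:, 2] > 0
            if valid.sum() >= 2:
                area = float(np.ptp(arr[valid, 0]) * np.ptp(arr[valid, 1]))
            else:
                area = 0.0
            if area > best_area:
                best, best_area = arr, area
        if best is not None:
            pts[i] = best[:, :2]
            conf[i] = np.clip(best[:, 2], 0.0, 1.0)
    return KeypointSequence(fps=fps, points=pts, confidence=conf, image_height=image_height)


# ---------------------------------------------------------------------------
# frame filtering


@dataclass
class FilteredSequence:
    """The longest contiguous run of frames passing the confidence filter."""

    sequence: KeypointSequence  # only the retained run
    frame_indices: np.ndarray  # indices of the run in the original sequence
    retained_fraction: float  # fraction of *all* frames passing the filter
    side: str


def choose_side(seq: KeypointSequence, conf_threshold: float = 0.3) -> str:
    """Camera-facing side: the side with higher mean keypoint confidence."""
    scores = {}
    for side in ("right", "left"):
        idx = [j for j in body25.required_points(side) if j not in body25.CENTRAL_POINTS]
        scores[side] = float(seq.confidence[:, idx].mean())
    return max(scores, key=scores.get)


def filter_frames(
    seq: KeypointSequence,
    required_points: Sequence[int] | None = None,
    conf_threshold: float = 0.3,
    cadence_estimate: float = 2.0,
) -> FilteredSequence:
    """Retain frames in which every required point is confidently detected.

    Frames where the walker is entering or leaving the field of view
    have incomplete detections and are dropped.  The longest contiguous
    retained run feeds the time-series parameters; it must span at
    least one gait cycle (two steps at the cadence estimate), else
    :class:`InsufficientFramesError` is raised.
    """
    side = choose_side(seq, conf_threshold)
    if required_points is None:
        required_points = body25.required_points(side)
    required_points = list(required_points)
    if any(j < 0 or j >= body25.N_KEYPOINTS for j in required_points):
        raise ParameterError("required_points must be BODY_25 indices")
    mask = np.all(seq.confidence[:, required_points] >= conf_threshold, axis=1)
    fraction = float(mask.mean()) if mask.size else 0.0
    # longest contiguous True run
    best_start, best_len, start = 0, 0, None
    for i, ok in enumerate(mask):
        if ok and start is None:
            start = i
        if (not ok or i == mask.size - 1) and start is not None:
            end = i + 1 if ok else i
            if end - start > best_len:
                best_start, best_len = start, end - start
            start = None
    min_run = max(2, int(math.ceil(2.0 * seq.fps / cadence_estimate)))
    if best_len < min_run:
        raise InsufficientFramesError(
            f"longest usable run is {best_len} frames; need {min_run} "
            f"(one gait cycle at {cadence_estimate} steps/s)"
        )
    indices = np.arange(best_start, best_start + best_len)
    return FilteredSequence(
        sequence=seq.subset(indices),
        frame_indices=indices,
        retained_fraction=fraction,
        side=side,
    )


# ---------------------------------------------------------------------------
# geometry


def _interior_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Interior angle at b between rays b->a and b->c, degrees, vectorized."""
    a, b, c = (np.asarray(v, dtype=float) for v in (a, b, c))
    u = a - b
    v = c - b
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu == 0) or np.any(nv == 0):
        raise DegenerateGeometryError("coincident keypoints")
    cos = np.sum(u * v, axis=-1) / (nu * nv)
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def _reference_angle(p: np.ndarray, q: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Angle between segment p->q and a reference direction, degrees."""
    p, q = np.asarray(p, dtype=float), np.asarray(q, dtype=float)
    d = q - p
    nd = np.linalg.norm(d, axis=-1)
    if np.any(nd == 0):
        raise DegenerateGeometryError("coincident keypoints")
    cos = np.sum(d * ref, axis=-1) / (nd * np.linalg.norm(ref))
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def joint_angle(a, b, c) -> float:
    """Interior angle at ``b`` between rays ``b->a`` and ``b->c``.

    Points are 2D world coordinates (y up).  Collinear points give
    180 degrees, a right angle 90.
    """
    return float(_interior_angle(np.atleast_1d(a), np.atleast_1d(b), np.atleast_1d(c)))


def segment_reference_angle(
    p, q, reference: str = "vertical", travel_sign: float = 1.0
) -> float:
    """Angle in [0, 180] between segment p->q and a reference direction.

    ``reference`` is ``"vertical"`` (up, in world coordinates) or
    ``"horizontal"`` (the direction of travel; ``travel_sign`` is +1
    for walking toward +x, -1 otherwise).
    """
    if reference == "vertical":
        ref = np.array([0.0, 1.0])
    elif reference == "horizontal":
        ref = np.array([float(np.sign(travel_sign) or 1.0), 0.0])
    else:
        raise ParameterError("reference must be 'vertical' or 'horizontal'")
    return float(_reference_angle(np.atleast_1d(p), np.atleast_1d(q), ref))


# ---------------------------------------------------------------------------
# wavelet denoising


def wavelet_denoise(
    values: np.ndarray,
    wavelet: str = "db4",
    level: int = 3,
    mode: str = "soft",
    threshold: float | None = None,
) -> np.ndarray:
    """Wavelet-denoise an angle trajectory.

    3-level discrete wavelet decomposition with the Daubechies-4
    filter and symmetric boundary extension.  In ``"soft"`` mode the
    detail coefficients are soft-thresholded with the universal
    threshold ``sigma * sqrt(2 ln N)`` where ``sigma`` is the robust
    MAD estimate from the finest detail band; ``"approx"`` keeps only
    the approximation band.  Series shorter than 16 samples (too short
    to support 3 Daubechies-4 levels) are returned unchanged with a
    logged warning.  ``threshold`` overrides the universal threshold.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 16:
        log.warning("series of length %d too short for %s level-%d denoising", n, wavelet, level)
        return x.copy()
    coeffs = pywt.wavedec(x, wavelet, level=level, mode="symmetric")
    if mode == "approx":
        details = [np.zeros_like(c) for c in coeffs[1:]]
    elif mode == "soft":
        if threshold is None:
            sigma = float(np.median(np.abs(coeffs[-1]))) / 0.6745
            threshold = sigma * math.sqrt(2.0 * math.log(n))
        details = [pywt.threshold(c, threshold, mode="soft") for c in coeffs[1:]]
    else:
        raise ParameterError("mode must be 'soft' or 'approx'")
    rec = pywt.waverec([coeffs[0]] + details, wavelet, mode="symmetric")
    return rec[:n]


# ---------------------------------------------------------------------------
# angle series


def _world_points(seq: KeypointSequence) -> np.ndarray:
    """Keypoints in world coordinates: x unchanged, y flipped to point up."""
    w = seq.points.copy()
    w[:, :, 1] = seq.image_height - w[:, :, 1]
    return w


def _travel_sign(world: np.ndarray) -> float:
    dx = world[-1, body25.MID_HIP, 0] - world[0, body25.MID_HIP, 0]
    return 1.0 if dx >= 0 else -1.0


def posture_angle_series(
    fseq: FilteredSequence, config: VideoConfig = DEFAULT_VIDEO_CONFIG
) -> dict[str, AngleSeries]:
    """Per-frame angle trajectories on the camera-facing side.

    Returns the raw (un-denoised) series; callers denoise before
    summarising.  The head point is the camera-side ear unless its mean
    confidence fails the threshold, in which case the nose is used.
    """
    seq = fseq.sequence
    side = fseq.side
    j = body25.SIDE_JOINTS[side]
    world = _world_points(seq)
    sign = _travel_sign(world)
    href = np.array([sign, 0.0])
    vref = np.array([0.0, 1.0])

    nose = world[:, body25.NOSE]
    neck = world[:, body25.NECK]
    midhip = world[:, body25.MID_HIP]
    shoulder = world[:, j["shoulder"]]
    elbow = world[:, j["elbow"]]
    wrist = world[:, j["wrist"]]
    hip = world[:, j["hip"]]
    knee = world[:, j["knee"]]
    ankle = world[:, j["ankle"]]
    toe = world[:, j["big_toe"]]
    ear = world[:, j["ear"]]
    ear_ok = seq.confidence[:, j["ear"]].mean() >= config.conf_threshold
    head_pt = ear if ear_ok else nose

    series = {
        "knee": _interior_angle(hip, knee, ankle),
        "ankle": _interior_angle(knee, ankle, toe),
        "elbow": _interior_angle(shoulder, elbow, wrist),
        "upper_arm_trunk": _interior_angle(elbow, shoulder, midhip),
        "trunk_thigh": _interior_angle(neck, midhip, knee),
        "neck_trunk": _interior_angle(head_pt, neck, midhip),
        "body_lean": _reference_angle(midhip, neck, vref),
        "sight_line": _reference_angle(ear, nose, href),
        "head_to_body": _interior_angle(head_pt, neck, midhip),
        "head_to_ground": _reference_angle(neck, head_pt, href),
        "calf_to_vertical": _reference_angle(knee, ankle, vref),
    }
    return {
        name: AngleSeries(name=name, values=vals, frame_indices=fseq.frame_indices)
        for name, vals in series.items()
    }


# ---------------------------------------------------------------------------
# spatiotemporal parameters


@dataclass(frozen=True)
class SpatioTemporal:
    heel_height_m: float
    step_length_m: float
    step_speed_mps: float
    cadence_steps_per_s: float
    scale_m_per_px: float


def spatiotemporal_params(
    fseq: FilteredSequence,
    walkway_length: float = 5.0,
    config: VideoConfig = DEFAULT_VIDEO_CONFIG,
) -> SpatioTemporal:
    """Heel height, step length, step speed and cadence.

    The pixel-to-metre scale equates the horizontal mid-hip
    displacement over the retained run with ``walkway_length``.  Heel
    strikes are the local maxima of the horizontal ankle-to-ankle
    separation; step length is the mean horizontal distance between
    consecutive alternating strike positions; step speed is step
    length x cadence by definition.  Heel height is the mean per-cycle
    maximum heel clearance above the ground line (the lowest heel
    position seen in the run).
    """
    if walkway_length <= 0:
        raise ParameterError("walkway_length must be positive")
    seq = fseq.sequence
    fps = seq.fps
    world = _world_points(seq)
    sign = _travel_sign(world)
    disp = abs(world[-1, body25.MID_HIP, 0] - world[0, body25.MID_HIP, 0])
    if disp == 0:
        raise DegenerateGeometryError("no hip displacement; cannot set the scale")
    scale = walkway_length / disp  # metres per pixel

    xr = world[:, body25.R_ANKLE, 0]
    xl = world[:, body25.L_ANKLE, 0]
    sep = np.abs(xr - xl)
    distance = max(1, int(round(0.6 * fps / config.cadence_estimate)))
    prom = 0.15 * float(np.ptp(sep)) if np.ptp(sep) > 0 else None
    peaks, _ = find_peaks(sep, distance=distance, prominence=prom)
    if peaks.size < 2:
        raise InsufficientStepsError(f"only {peaks.size} heel strikes found")

    lead = np.where(sign * (xr - xl) >= 0, xr, xl)  # leading-ankle x per frame
    strike_x = lead[peaks]
    step_length = float(np.mean(np.abs(np.diff(strike_x)))) * scale
    cadence = (peaks.size - 1) / ((peaks[-1] - peaks[0]) / fps)
    step_speed = step_length * cadence

    j = body25.SIDE_JOINTS[fseq.side]
    heel_y = world[:, j["heel"], 1]
    ground = float(heel_y.min())
    clearance = heel_y - ground
    # gait cycles delimited by camera-side strikes (every other strike)
    cam_ankle = xr if fseq.side == "right" else xl
    other = xl if fseq.side == "right" else xr
    cam_strikes = peaks[sign * (cam_ankle[peaks] - other[peaks]) >= 0]
    if cam_strikes.size >= 2:
        maxima = [
            float(clearance[a:b + 1].max())
            for a, b in zip(cam_strikes[:-1], cam_strikes[1:])
        ]
        heel_height = float(np.mean(maxima)) * scale
    else:
        heel_height = float(clearance.max()) * scale
    return SpatioTemporal(
        heel_height_m=heel_height,
        step_length_m=step_length,
        step_speed_mps=step_speed,
        cadence_steps_per_s=float(cadence),
        scale_m_per_px=scale,
    )


# ---------------------------------------------------------------------------
# orchestration


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except StageError:
        raise
    except GaitmixError as exc:
        raise StageError(name, exc) from exc


def extract_posture_features(
    seq: KeypointSequence,
    walkway_length: float = 5.0,
    config: VideoConfig = DEFAULT_VIDEO_CONFIG,
) -> PostureFeatures:
    """Run the full video pipeline on one keypoint sequence.

    filter -> angle series -> wavelet denoise -> mean/variance for the
    five dynamic joint angles and mean for the six postural angles,
    plus the spatiotemporal parameters.  Stage failures re-raise as
    :class:`StageError` with the stage name.
    """
    fseq = _stage(
        "filter",
        filter_frames,
        seq,
        None,
        config.conf_threshold,
        config.cadence_estimate,
    )
    raw = _stage("angles", posture_angle_series, fseq, config)
    den = {
        name: wavelet_denoise(
            s.values, config.wavelet, config.wavelet_level, config.denoise_mode
        )
        for name, s in raw.items()
    }
    st = _stage("spatiotemporal", spatiotemporal_params, fseq, walkway_length, config)

    def mv(name: str) -> tuple[float, float]:
        v = den[name]
        return float(v.mean()), float(v.var(ddof=1)) if v.size > 1 else 0.0

    return PostureFeatures(
        knee_mean=mv("knee")[0],
        knee_var=mv("knee")[1],
        ankle_mean=mv("ankle")[0],
        ankle_var=mv("ankle")[1],
        elbow_mean=mv("elbow")[0],
        elbow_var=mv("elbow")[1],
        upper_arm_trunk_mean=mv("upper_arm_trunk")[0],
        upper_arm_trunk_var=mv("upper_arm_trunk")[1],
        trunk_thigh_mean=mv("trunk_thigh")[0],
        trunk_thigh_var=mv("trunk_thigh")[1],
        neck_trunk_mean=float(den["neck_trunk"].mean()),
        body_lean_mean=float(den["body_lean"].mean()),
        sight_line_mean=float(den["sight_line"].mean()),
        head_to_body_mean=float(den["head_to_body"].mean()),
        head_to_ground_mean=float(den["head_to_ground"].mean()),
        calf_to_vertical_mean=float(den["calf_to_vertical"].mean()),
        heel_height_m=st.heel_height_m,
        step_length_m=st.step_length_m,
        step_speed_mps=st.step_speed_mps,
        cadence_steps_per_s=st.cadence_steps_per_s,
        retained_frame_fraction=fseq.retained_fraction,
        side=fseq.side,
    )
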