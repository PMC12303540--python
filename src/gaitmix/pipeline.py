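"""Batch orchestration: cohort materialisation, extraction, comparison.

Per-recording failures during extraction are data, not crashes: they
are collected into an exclusion table with the failing stage and
reason, mirroring how a clinical study accounts for incomplete
recordings, and the run continues.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__, io
from .errors import DesignError, GaitmixError, StageError
from .sensor import DEFAULT_SENSOR_CONFIG, SensorConfig, extract_sensor_features
from .synthetic import CohortData, CohortDesign, simulate_cohort
from .video import DEFAULT_VIDEO_CONFIG, VideoConfig, extract_posture_features, parse_openpose_json

log = logging.getLogger(__name__)

METADATA_COLUMNS = (
    "participant",
    "group",
    "task",
    "repetition",
    "sex",
    "age_years",
    "height_cm",
    "weight_kg",
    "bmi",
)


@dataclass
class ExtractionResult:
    features: pd.DataFrame
    exclusions: pd.DataFrame


def extract_cohort_features(
    cohort: CohortData,
    sensor_config: SensorConfig = DEFAULT_SENSOR_CONFIG,
    video_config: VideoConfig = DEFAULT_VIDEO_CONFIG,
    walkway_length: float = 5.0,
    include_video: bool = True,
) -> ExtractionResult:
    """Run both pipelines over an in-memory cohort.

    Returns a feature row per recording (sensor and video columns
    merged) plus the exclusion table.  A recording whose sensor *and*
    video extraction both fail contributes no feature row.
    """
    rows, excl = [], []
    for rec in cohort.records:
        key = {
            "participant": rec.participant,
            "group": rec.group,
            "task": rec.task,
            "repetition": rec.repetition,
        }
        row = dict(key)
        ok = False
        try:
            res = extract_sensor_features(rec.accel.recording, sensor_config)
            row.update(res.features.as_dict())
            ok = True
        except (StageError, GaitmixError) as exc:
            stage = getattr(exc, "stage", "sensor")
            excl.append({**key, "stream": "sensor", "stage": stage, "reason": str(exc)})
        if include_video:
            try:
                pf = extract_posture_features(
                    rec.video.sequence, walkway_length, video_config
                )
                row.update(pf.as_dict())
                row["side"] = pf.side
                ok = True
            except (StageError, GaitmixError) as exc:
                stage = getattr(exc, "stage", "video")
                excl.append({**key, "stream": "video", "stage": stage, "reason": str(exc)})
        if ok:
            rows.append(row)
    features = pd.DataFrame(rows)
    if not features.empty:
        meta_cols = [c for c in cohort.metadata.columns if c in METADATA_COLUMNS]
        features = features.merge(
            cohort.metadata[meta_cols].drop_duplicates(
                ["participant", "task", "repetition"]
            ),
            on=["participant", "group", "task", "repetition"],
            how="left",
        )
    exclusions = pd.DataFrame(
        excl, columns=["participant", "group", "task", "repetition", "stream", "stage", "reason"]
    )
    return ExtractionResult(features=features, exclusions=exclusions)


# ---------------------------------------------------------------------------
# disk layout


def write_cohort(cohort: CohortData, out_dir: str | Path) -> dict:
    """Materialise a cohort as accelerometer CSVs + keypoint JSON dirs.

    Returns the manifest (also written to ``manifest.json``), which
    records the design, seed, file inventory and a content hash so
    reruns can be verified byte-identical.
    """
    out = Path(out_dir)
    (out / "accel").mkdir(parents=True, exist_ok=True)
    (out / "video").mkdir(parents=True, exist_ok=True)
    design_dict = design_to_dict(cohort.design)
    config_sha = io.sha256_of(design_dict)
    meta = cohort.metadata.copy()
    accel_paths, video_dirs, fps_list, imh_list = [], [], [], []
    files: list[Path] = []
    for rec in cohort.records:
        stem = f"{rec.participant}_{rec.task}_{rec.repetition}"
        apath = out / "accel" / f"{stem}.csv"
        io.write_accelerometer_csv(
            apath, rec.accel.recording, seed=cohort.design.seed, config_sha=config_sha
        )
        vdir = out / "video" / stem
        frame_paths = io.write_keypoint_frames(vdir, rec.video.sequence)
        accel_paths.append(str(apath.relative_to(out)))
        video_dirs.append(str(vdir.relative_to(out)))
        fps_list.append(rec.video.sequence.fps)
        imh_list.append(rec.video.sequence.image_height)
        files.append(apath)
        files.extend(frame_paths)
    meta["accel_path"] = accel_paths
    meta["video_dir"] = video_dirs
    meta["fps"] = fps_list
    meta["image_height"] = imh_list
    io.write_table_csv(out / "metadata.csv", meta, seed=cohort.design.seed, config_sha=config_sha)
    files.append(out / "metadata.csv")

    import hashlib

    h = hashlib.sha256()
    for f in sorted(files):
        h.update(str(f.relative_to(out)).encode())
        h.update(bytes.fromhex(io.file_sha256(f)))
    manifest = {
        "version": __version__,
        "seed": cohort.design.seed,
        "design": design_dict,
        "design_sha": config_sha,
        "n_records": len(cohort.records),
        "n_files": len(files),
        "content_sha256": h.hexdigest(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def extract_from_disk(
    data_dir: str | Path,
    sensor_config: SensorConfig = DEFAULT_SENSOR_CONFIG,
    video_config: VideoConfig = DEFAULT_VIDEO_CONFIG,
    walkway_length: float = 5.0,
) -> ExtractionResult:
    """Run both pipelines over a materialised dataset directory."""
    data = Path(data_dir)
    meta_path = data / "metadata.csv"
    if not meta_path.exists():
        raise DesignError(f"no metadata.csv under {data}")
    meta = io.read_table_csv(meta_path)
    if meta.empty:
        raise DesignError("empty dataset")
    rows, excl = [], []
    t0 = time.perf_counter()
    for _, m in meta.iterrows():
        key = {
            "participant": m["participant"],
            "group": m["group"],
            "task": m["task"],
            "repetition": int(m["repetition"]),
        }
        row = dict(key)
        for col in METADATA_COLUMNS[4:]:
            if col in meta.columns:
                row[col] = m[col]
        ok = False
        try:
            rec = io.read_accelerometer_csv(data / m["accel_path"])
            res = extract_sensor_features(rec, sensor_config)
            row.update(res.features.as_dict())
            ok = True
        except (StageError, GaitmixError) as exc:
            stage = getattr(exc, "stage", "sensor")
            excl.append({**key, "stream": "sensor", "stage": stage, "reason": str(exc)})
        try:
            frames = io.list_keypoint_frames(data / m["video_dir"])
            seq = parse_openpose_json(
                frames, fps=float(m.get("fps", 60.0)), image_height=float(m.get("image_height", 1080.0))
            )
            pf = extract_posture_features(seq, walkway_length, video_config)
            row.update(pf.as_dict())
            row["side"] = pf.side
            ok = True
        except (StageError, GaitmixError) as exc:
            stage = getattr(exc, "stage", "video")
            excl.append({**key, "stream": "video", "stage": stage, "reason": str(exc)})
        if ok:
            rows.append(row)
    log.info("extracted %d recordings in %.1f s", len(rows), time.perf_counter() - t0)
    return ExtractionResult(
        features=pd.DataFrame(rows),
        exclusions=pd.DataFrame(
            excl,
            columns=["participant", "group", "task", "repetition", "stream", "stage", "reason"],
        ),
    )


# ---------------------------------------------------------------------------
# design (de)serialisation


def design_to_dict(design: CohortDesign) -> dict:
    d = dataclasses.asdict(design)

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        return obj

    return clean(d)


def design_from_dict(d: dict) -> CohortDesign:
    from .synthetic import GaitSimParams, GroupSpec, PostureSimParams, TaskOffsets

    def group(gd: dict) -> GroupSpec:
        return GroupSpec(
            gait=GaitSimParams(**gd["gait"]),
            posture=PostureSimParams(**gd["posture"]),
            gait_sd=dict(gd.get("gait_sd", {})),
            posture_sd=dict(gd.get("posture_sd", {})),
            demographics={k: tuple(v) for k, v in gd.get("demographics", {}).items()},
            male_fraction=gd.get("male_fraction", 0.5),
        )

    def offsets(entry):
        if set(entry) <= {"gait", "posture"}:
            return TaskOffsets(
                gait=dict(entry.get("gait", {})), posture=dict(entry.get("posture", {}))
            )
        return {g: offsets(sub) for g, sub in entry.items()}

    return CohortDesign(
        n_control=int(d["n_control"]),
        n_csvd=int(d["n_csvd"]),
        control=group(d["control"]),
        csvd=group(d["csvd"]),
        tasks={t: offsets(e) for t, e in d["tasks"].items()},
        repetitions=int(d.get("repetitions", 2)),
        seed=int(d.get("seed", 0)),
    )


def simulate_to_disk(design: CohortDesign, out_dir: str | Path) -> dict:
    """Simulate a cohort from a design and write it to disk."""
    cohort = simulate_cohort(design)
    return write_cohort(cohort, out_dir)
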