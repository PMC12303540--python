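"""File formats: accelerometer CSV, per-frame keypoint JSON, feature tables.

Accelerometer CSV: columns ``t_s, ax, ay, az`` (SI units) with ``#``
header comment lines carrying version/seed provenance.  Keypoint files
use the standard pose-estimator dialect -- one JSON file per frame,
``{"version": 1.3, "people": [{"pose_keypoints_2d": [x0, y0, c0, ...]}]}``
with a zero-padded frame index in the filename -- so output from a
real estimator drops in unchanged.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import FormatError
from .types import AccelerometerRecording, KeypointSequence


def _header_comment(seed: int | None, config_sha: str | None) -> str:
    parts = [f"# gaitmix v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_sha is not None:
        parts.append(f"config_sha={config_sha}")
    return " ".join(parts) + "\n"


def sha256_of(obj) -> str:
    """Stable hash of a JSON-serialisable object (short hex digest)."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_accelerometer_csv(
    path: str | Path,
    rec: AccelerometerRecording,
    seed: int | None = None,
    config_sha: str | None = None,
) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "t_s": rec.timestamps,
            "ax": rec.acceleration[:, 0],
            "ay": rec.acceleration[:, 1],
            "az": rec.acceleration[:, 2],
        }
    )
    with open(path, "w") as fh:
        fh.write(_header_comment(seed, config_sha))
        df.to_csv(fh, index=False, float_format="%.9g")


def read_accelerometer_csv(path: str | Path) -> AccelerometerRecording:
    df = pd.read_csv(path, comment="#")
    missing = {"t_s", "ax", "ay", "az"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return AccelerometerRecording(
        timestamps=df["t_s"].to_numpy(),
        acceleration=df[["ax", "ay", "az"]].to_numpy(),
    )


def write_keypoint_frames(
    out_dir: str | Path, seq: KeypointSequence, prefix: str = "frame"
) -> list[Path]:
    """Write one JSON file per frame; returns the file paths in order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(seq.n_frames):
        flat = []
        for j in range(seq.points.shape[1]):
            flat.extend(
                [
                    float(seq.points[i, j, 0]),
                    float(seq.points[i, j, 1]),
                    float(seq.confidence[i, j]),
                ]
            )
        doc = {"version": 1.3, "people": [{"person_id": [-1], "pose_keypoints_2d": flat}]}
        path = out_dir / f"{prefix}_{i:012d}_keypoints.json"
        with open(path, "w") as fh:
            json.dump(doc, fh)
        paths.append(path)
    return paths


def list_keypoint_frames(video_dir: str | Path) -> list[Path]:
    paths = sorted(Path(video_dir).glob("*_keypoints.json"))
    if not paths:
        raise FormatError(f"no *_keypoints.json files under {video_dir}")
    return paths


def write_table_csv(
    path: str | Path,
    df: pd.DataFrame,
    seed: int | None = None,
    config_sha: str | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(seed, config_sha))
        df.to_csv(fh, index=False)


def read_table_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
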