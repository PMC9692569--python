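"""File formats: calibration, image stacks, poses, geometry, trajectories.

All formats are plain text or standard image containers.  The pixel
convention for calibration matrices is documented in
:mod:`flypose.projection`: (i, j) = (column, row), 0-based, origin at the
centre of the top-left pixel; matrices are stored row-major.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .fly_model import POSE_FIELDS, POSE_UNITS, FlyGeometry, PoseVector17
from .loss import LossValue
from .projection import CameraModel
from .segmentation import Frame
from .tracker import FrameRecord, TrackRecord

TRAJECTORY_MAGIC = "# flypose trajectory v1"


# ---------------------------------------------------------------------------
# calibration


def write_calibration(cameras: List[CameraModel], path) -> None:
    """Write cameras as structured text: label, image size, 3x4 row-major."""
    lines = ["# flypose calibration: 3x4 projection matrices, row-major",
             "# pixel convention: (i, j) = (column, row), 0-based"]
    for cam in cameras:
        lines.append(f"camera {cam.label}")
        lines.append(f"size {cam.image_width} {cam.image_height}")
        for row in cam.M:
            lines.append(" ".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_calibration(path) -> List[CameraModel]:
    """Read and validate a calibration file written by
    :func:`write_calibration`; malformed lines are rejected with their
    line number, rank-deficient matrices are rejected by the camera
    constructor."""
    cameras = []
    label, size, rows = None, None, []

    def flush(lineno):
        nonlocal label, size, rows
        if label is None:
            return
        if size is None or len(rows) != 3:
            raise ValueError(f"camera '{label}' incomplete before line {lineno}")
        cameras.append(CameraModel(M=np.array(rows), image_width=size[0],
                                   image_height=size[1], label=label))
        label, size, rows = None, None, []

    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("camera "):
            flush(lineno)
            label = line.split(maxsplit=1)[1]
        elif line.startswith("size "):
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"line {lineno}: malformed size line")
            size = (int(parts[1]), int(parts[2]))
        else:
            try:
                vals = [float(v) for v in line.split()]
            except ValueError as e:
                raise ValueError(f"line {lineno}: malformed matrix row") from e
            if len(vals) != 4:
                raise ValueError(f"line {lineno}: matrix row needs 4 values, "
                                 f"got {len(vals)}")
            rows.append(vals)
    flush("end of file")
    if not cameras:
        raise ValueError(f"no cameras found in {path}")
    return cameras


# ---------------------------------------------------------------------------
# image stacks


_NUM_RE = re.compile(r"(\d+)")


def _frame_index(name: str) -> int:
    m = _NUM_RE.findall(name)
    if not m:
        raise ValueError(f"cannot extract a frame index from '{name}'")
    return int(m[-1])


def read_frames(directory, camera_label: str) -> List[Frame]:
    """Read a numbered image sequence (PNG/TIFF) as normalized frames.

    Files are ordered by the last integer in their stem; indices must be
    contiguous.  Integer images are normalized by their dtype maximum.
    """
    directory = Path(directory)
    paths = sorted((p for p in directory.iterdir()
                    if p.suffix.lower() in (".png", ".tif", ".tiff")),
                   key=lambda p: _frame_index(p.stem))
    if not paths:
        raise ValueError(f"no image files in {directory}")
    indices = [_frame_index(p.stem) for p in paths]
    expect = list(range(indices[0], indices[0] + len(paths)))
    if indices != expect:
        missing = sorted(set(expect) - set(indices))
        raise ValueError(f"missing frame indices in {directory}: {missing}")
    frames = []
    for k, p in enumerate(paths):
        img = np.asarray(iio.imread(p))
        if img.ndim == 3:
            img = img[..., :3].mean(axis=-1)
        if np.issubdtype(img.dtype, np.integer):
            img = img.astype(float) / np.iinfo(img.dtype).max
        frames.append(Frame(np.clip(img.astype(float), 0.0, 1.0),
                            index=k, camera_label=camera_label))
    return frames


def write_stack(stack: np.ndarray, directory, prefix: str = "frame") -> None:
    """Write a (T, H, W) float [0,1] stack as 16-bit PNG files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k, img in enumerate(stack):
        arr = np.clip(img, 0.0, 1.0)
        iio.imwrite(directory / f"{prefix}_{k:05d}.png",
                    (arr * 65535).astype(np.uint16))


def write_masks(masks: List, directory, prefix: str = "mask") -> None:
    """Write binary masks as 8-bit PNGs for inspection."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k, m in enumerate(masks):
        arr = m.mask if hasattr(m, "mask") else m
        iio.imwrite(directory / f"{prefix}_{k:05d}.png",
                    (np.asarray(arr, dtype=np.uint8) * 255))


# ---------------------------------------------------------------------------
# poses and geometry


def write_pose(pose: PoseVector17, path) -> None:
    """Write a pose as YAML, one ``field: value`` entry per DOF."""
    data = {f: float(getattr(pose, f)) for f in POSE_FIELDS}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_pose(path) -> PoseVector17:
    data = yaml.safe_load(Path(path).read_text())
    unknown = set(data) - set(POSE_FIELDS)
    if unknown:
        raise ValueError(f"unknown pose fields in {path}: {sorted(unknown)}")
    return PoseVector17(**{k: float(v) for k, v in data.items()})


def write_geometry(geometry: FlyGeometry, path) -> None:
    data = {
        "body_vertices": geometry.body_vertices.tolist(),
        "body_faces": geometry.body_faces.tolist(),
        "wing_outline": geometry.wing_outline.tolist(),
        "span_length": geometry.span_length,
        "rest_hinge_left": geometry.rest_hinge_left.tolist(),
        "rest_hinge_right": geometry.rest_hinge_right.tolist(),
        "scale": geometry.scale,
        "stroke_plane_angle": geometry.stroke_plane_angle,
        "rod_vertices": (geometry.rod_vertices.tolist()
                         if geometry.rod_vertices is not None else None),
    }
    Path(path).write_text(json.dumps(data))


def read_geometry(path) -> FlyGeometry:
    data = json.loads(Path(path).read_text())
    rod = data.pop("rod_vertices", None)
    return FlyGeometry(
        body_vertices=np.array(data["body_vertices"]),
        body_faces=np.array(data["body_faces"]),
        wing_outline=np.array(data["wing_outline"]),
        span_length=data["span_length"],
        rest_hinge_left=np.array(data["rest_hinge_left"]),
        rest_hinge_right=np.array(data["rest_hinge_right"]),
        scale=data["scale"],
        stroke_plane_angle=data["stroke_plane_angle"],
        rod_vertices=np.array(rod) if rod is not None else None,
    )


# ---------------------------------------------------------------------------
# trajectories


def write_trajectory(records: TrackRecord, path,
                     header_extra: Optional[Dict] = None) -> None:
    """Write a tracked sequence as CSV with a documented units header."""
    units = "; ".join(f"{f} [{POSE_UNITS[f]}]" for f in POSE_FIELDS)
    lines = [TRAJECTORY_MAGIC, f"# units: {units}"]
    if header_extra:
        lines.append("# config: " + json.dumps(header_extra, sort_keys=True))
    df = records.to_dataframe()
    csv = df.to_csv(index=False, lineterminator="\n")
    Path(path).write_text("\n".join(lines) + "\n" + csv)


def read_trajectory(path) -> TrackRecord:
    """Read a trajectory CSV back into a :class:`TrackRecord`."""
    text = Path(path).read_text().splitlines()
    if not text or text[0].strip() != TRAJECTORY_MAGIC:
        raise ValueError(f"{path} is not a flypose trajectory file")
    body = [ln for ln in text if not ln.startswith("#")]
    from io import StringIO
    df = pd.read_csv(StringIO("\n".join(body)))
    missing = [f for f in POSE_FIELDS if f not in df.columns]
    if missing:
        raise ValueError(f"trajectory header mismatch, missing {missing}")
    loss_cols = [c for c in df.columns if c.startswith("loss_")
                 and c != "loss_total"]
    records = TrackRecord()
    for _, row in df.iterrows():
        pose = PoseVector17(**{f: float(row[f]) for f in POSE_FIELDS})
        per_view = {c[len("loss_"):]: float(row[c]) for c in loss_cols}
        lv = LossValue(total=float(row["loss_total"]), per_view=per_view)
        records.append(FrameRecord(
            index=int(row["frame"]), pose=pose, loss=lv, init_pose=pose,
            anomaly=bool(row.get("anomaly", 0)),
            corrected=bool(row.get("corrected", 0)),
            failed=bool(row.get("failed", 0)),
            n_evals=int(row.get("n_evals", 0))))
    return records


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Resolved configuration of one tracking run."""

    frames_dir: str
    calibration: str
    init_pose: str
    out: str
    geometry: Optional[str] = None
    seed: int = 0
    roll_window: float = 2.0
    rigid: bool = False
    psi_jump_threshold: float = 15.0
    loss_jump_threshold: float = 0.5
    n_starts: int = 15
    n_candidates: int = 10_000
    backtrack_depth: int = 5
    keep_largest_component: bool = True
    log_level: str = "INFO"

    def to_dict(self) -> Dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; referenced input paths must exist."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(data) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    for key in ("frames_dir", "calibration", "init_pose", "geometry"):
        val = getattr(cfg, key)
        if val is not None and not Path(val).exists():
            raise FileNotFoundError(f"config path '{key}' does not exist: {val}")
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
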