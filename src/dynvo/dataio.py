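"""Readers and writers for the on-disk formats the toolkit exchanges.

Formats: Middlebury ``.flo`` dense flow, TUM trajectory text files
(translations in mm here, documented in a header comment), YAML intrinsics,
16-bit PNG depth with the scale factor in a sidecar/meta YAML, and 8-bit PNG
motion-probability maps (value/255 = probability).
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .geometry import CameraIntrinsics, FlowField, RelativePose, Trajectory

__all__ = [
    "read_flo",
    "write_flo",
    "read_tum",
    "write_tum",
    "read_intrinsics",
    "write_intrinsics",
    "read_depth_png",
    "write_depth_png",
    "read_motion_png",
    "write_motion_png",
]

_FLO_MAGIC = 202021.25


def write_flo(path: str | os.PathLike, flow: FlowField | np.ndarray) -> None:
    """Write a flow field in the Middlebury .flo binary layout."""
    arr = flow.flow if isinstance(flow, FlowField) else np.asarray(flow)
    if arr.ndim != 3 or arr.shape[2] != 2:
        raise ValueError("flow must have shape (H, W, 2)")
    h, w = arr.shape[:2]
    with open(path, "wb") as f:
        np.float32(_FLO_MAGIC).tofile(f)
        np.int32(w).tofile(f)
        np.int32(h).tofile(f)
        arr.astype(np.float32).tofile(f)


def read_flo(path: str | os.PathLike, kind: str = "forward-temporal") -> FlowField:
    with open(path, "rb") as f:
        magic = np.fromfile(f, np.float32, 1)
        if magic.size != 1 or magic[0] != np.float32(_FLO_MAGIC):
            raise ValueError(f"{path}: not a Middlebury .flo file")
        w = int(np.fromfile(f, np.int32, 1)[0])
        h = int(np.fromfile(f, np.int32, 1)[0])
        data = np.fromfile(f, np.float32, h * w * 2)
    if data.size != h * w * 2:
        raise ValueError(f"{path}: truncated .flo file")
    return FlowField(data.reshape(h, w, 2).astype(float), kind=kind)


def write_tum(path: str | os.PathLike, traj: Trajectory) -> None:
    """Write a trajectory as TUM lines ``t tx ty tz qx qy qz qw`` (mm)."""
    with open(path, "w") as f:
        f.write("# timestamp tx ty tz qx qy qz qw  (translation in mm)\n")
        for ts, pose in zip(traj.timestamps, traj.poses):
            q = Rotation.from_matrix(pose.rotation).as_quat()  # x, y, z, w
            t = pose.translation
            f.write(
                f"{ts:.6f} {t[0]:.9f} {t[1]:.9f} {t[2]:.9f} "
                f"{q[0]:.9f} {q[1]:.9f} {q[2]:.9f} {q[3]:.9f}\n"
            )


def read_tum(path: str | os.PathLike) -> Trajectory:
    stamps, poses = [], []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            vals = [float(x) for x in line.split()]
            if len(vals) != 8:
                raise ValueError(f"{path}: malformed TUM line: {line!r}")
            stamps.append(vals[0])
            R = Rotation.from_quat(vals[4:8]).as_matrix()
            poses.append(RelativePose(R, np.array(vals[1:4])))
    if not poses:
        raise ValueError(f"{path}: empty trajectory file")
    return Trajectory(poses, np.array(stamps))


def write_intrinsics(path: str | os.PathLike, intr: CameraIntrinsics) -> None:
    data = {
        "fx": float(intr.fx),
        "fy": float(intr.fy),
        "cx": float(intr.cx),
        "cy": float(intr.cy),
        "width": int(intr.width),
        "height": int(intr.height),
        "baseline_mm": float(intr.baseline),
    }
    with open(path, "w") as f:
        yaml.safe_dump(data, f, sort_keys=True)


def read_intrinsics(path: str | os.PathLike) -> CameraIntrinsics:
    with open(path) as f:
        d = yaml.safe_load(f)
    return CameraIntrinsics(
        fx=d["fx"],
        fy=d["fy"],
        cx=d["cx"],
        cy=d["cy"],
        width=d["width"],
        height=d["height"],
        baseline=d["baseline_mm"],
    )


def write_depth_png(
    path: str | os.PathLike, depth_mm: np.ndarray, scale: float = 0.01
) -> None:
    """Store depth as 16-bit PNG; stored value * ``scale`` = depth in mm.

    Invalid (non-finite or non-positive) pixels are stored as 0.
    """
    d = np.asarray(depth_mm, dtype=float)
    counts = np.zeros(d.shape, dtype=np.uint16)
    ok = np.isfinite(d) & (d > 0)
    counts[ok] = np.clip(np.round(d[ok] / scale), 0, 65535).astype(np.uint16)
    iio.imwrite(path, counts)


def read_depth_png(path: str | os.PathLike, scale: float = 0.01) -> np.ndarray:
    counts = iio.imread(path).astype(float)
    depth = counts * scale
    depth[counts == 0] = np.nan
    return depth


def write_motion_png(path: str | os.PathLike, prob: np.ndarray) -> None:
    """Store a probability map in [0, 1] as 8-bit PNG (value/255)."""
    p = np.asarray(prob, dtype=float)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("motion probability must lie in [0, 1]")
    iio.imwrite(path, np.round(p * 255).astype(np.uint8))


def read_motion_png(path: str | os.PathLike) -> np.ndarray:
    return iio.imread(path).astype(float) / 255.0
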