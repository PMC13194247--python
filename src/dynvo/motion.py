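"""Per-pixel motion probabilities and the weights they induce.

The pose optimizer down-weights dynamic content with ``W = 1 - M``, where
``M`` is a per-pixel probability that the pixel belongs to independently
moving scene content.  ``M`` can come from ground-truth masks, from an
external file (e.g. a learned detector), or from the training-free
flow-consistency check implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    CameraIntrinsics,
    DepthMap,
    FlowField,
    RelativePose,
    backproject,
    project,
)

__all__ = [
    "MotionProbabilityMap",
    "WeightMap",
    "ValidityMask",
    "weight_from_motion",
    "constant_weight",
    "flow_consistency_motion",
    "fb_consistency_mask",
    "motion_iou",
    "motion_bce",
]

BCE_EPS = 1e-7


@dataclass
class MotionProbabilityMap:
    """H x W motion probabilities in [0, 1] with a provenance tag."""

    values: np.ndarray
    provenance: str = "ground-truth"  # "ground-truth" | "flow-consistency" | "external-file"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("motion probability must be a 2D grid")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("motion probability must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class WeightMap:
    """H x W residual weights in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("weight map must be a 2D grid")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("weights must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ValidityMask:
    """Binary grid of pixels usable for data association."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def weight_from_motion(M: MotionProbabilityMap | np.ndarray) -> WeightMap:
    """The complementary weight map ``W = 1 - M``."""
    values = M.values if isinstance(M, MotionProbabilityMap) else np.asarray(M, float)
    if np.any(values < 0) or np.any(values > 1):
        raise ValueError("motion probability must lie in [0, 1]")
    return WeightMap(1.0 - values)


def constant_weight(shape: tuple[int, int]) -> WeightMap:
    """The all-ones weight map: unweighted ("Naive") pose optimization."""
    return WeightMap(np.ones(shape))


def _sample_bilinear(grid: np.ndarray, uv: np.ndarray) -> np.ndarray:
    from scipy.ndimage import map_coordinates

    coords = np.stack([uv[..., 1].ravel(), uv[..., 0].ravel()])
    if grid.ndim == 2:
        return map_coordinates(grid.astype(float), coords, order=1, mode="nearest").reshape(
            uv.shape[:-1]
        )
    out = [
        map_coordinates(grid[..., c].astype(float), coords, order=1, mode="nearest")
        for c in range(grid.shape[-1])
    ]
    return np.stack(out, axis=-1).reshape(uv.shape[:-1] + (grid.shape[-1],))


def flow_consistency_motion(
    F_fwd: FlowField,
    D_t: DepthMap,
    pose_est: RelativePose,
    intr: CameraIntrinsics,
    sigma: float = 1.0,
) -> MotionProbabilityMap:
    """Training-free motion detection from rigid-flow consistency.

    Compares the observed forward flow with the flow the estimated pose
    would induce on the depth map; the discrepancy ``e`` (px) is mapped to a
    probability ``M = 1 - exp(-e^2 / (2 sigma^2))``.  Pixels where the check
    cannot be evaluated (invalid depth, behind-camera transform, flow target
    out of bounds) get ``M = 1`` so the optimizer excludes them.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    h, w = D_t.shape
    u, v = intr.pixel_grid()
    M = np.ones((h, w))
    valid = D_t.valid.copy()
    target = np.stack([u, v], axis=-1) + F_fwd.flow
    valid &= (
        (target[..., 0] >= 0)
        & (target[..., 0] <= w - 1)
        & (target[..., 1] >= 0)
        & (target[..., 1] <= h - 1)
    )
    if not valid.any():
        return MotionProbabilityMap(M, provenance="flow-consistency")
    depth = np.where(valid, D_t.depth, 1.0)
    X = backproject(np.stack([u, v], axis=-1), depth, intr)
    Xp = pose_est.apply(X)
    front = Xp[..., 2] > 0
    valid &= front
    proj = np.full((h, w, 2), np.nan)
    if front.any():
        proj[front] = project(Xp[front], intr)
    e = np.linalg.norm(target - proj, axis=-1)
    M[valid] = 1.0 - np.exp(-(e[valid] ** 2) / (2.0 * sigma**2))
    return MotionProbabilityMap(np.clip(M, 0.0, 1.0), provenance="flow-consistency")


def fb_consistency_mask(
    F_fwd: FlowField, F_bwd: FlowField, tau: float = 1.0
) -> ValidityMask:
    """Forward-backward flow consistency (occlusion) check.

    A pixel is valid when its forward-flow target lies in bounds and the
    round trip ``F_fwd(x) + F_bwd(x + F_fwd(x))`` (backward flow sampled
    bilinearly) has magnitude at most ``tau`` px.
    """
    if F_fwd.shape != F_bwd.shape:
        raise ValueError("flow fields must share a shape")
    h, w = F_fwd.shape
    v, u = np.mgrid[0:h, 0:w].astype(float)
    target = np.stack([u, v], axis=-1) + F_fwd.flow
    inb = (
        (target[..., 0] >= 0)
        & (target[..., 0] <= w - 1)
        & (target[..., 1] >= 0)
        & (target[..., 1] <= h - 1)
    )
    bwd_at_target = _sample_bilinear(F_bwd.flow, target)
    err = np.linalg.norm(F_fwd.flow + bwd_at_target, axis=-1)
    return ValidityMask(inb & (err <= tau))


def motion_iou(
    M: MotionProbabilityMap | np.ndarray,
    gt_mask: np.ndarray,
    threshold: float = 0.5,
) -> float:
    """Intersection-over-union (percent) of the binarized motion map.

    ``M`` is binarized at ``threshold``; if both the prediction and the
    ground truth are empty the IoU is defined as 100 (perfect agreement).
    """
    values = M.values if isinstance(M, MotionProbabilityMap) else np.asarray(M, float)
    gt = np.asarray(gt_mask, dtype=bool)
    if values.shape != gt.shape:
        raise ValueError("motion map and ground-truth mask shapes differ")
    pred = values >= threshold
    union = np.count_nonzero(pred | gt)
    if union == 0:
        return 100.0
    return 100.0 * np.count_nonzero(pred & gt) / union


def motion_bce(M: MotionProbabilityMap | np.ndarray, gt_mask: np.ndarray) -> float:
    """Mean binary cross-entropy between a motion map and a binary mask."""
    values = M.values if isinstance(M, MotionProbabilityMap) else np.asarray(M, float)
    gt = np.asarray(gt_mask, dtype=float)
    if values.shape != gt.shape:
        raise ValueError("motion map and ground-truth mask shapes differ")
    p = np.clip(values, BCE_EPS, 1.0 - BCE_EPS)
    return float(-np.mean(gt * np.log(p) + (1.0 - gt) * np.log(1.0 - p)))
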