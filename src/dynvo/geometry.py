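"""Pinhole stereo camera model and SE(3) pose algebra.

Conventions used throughout the package:

* pixels are 0-based, addressed at pixel centers; continuous (sub-pixel)
  coordinates are allowed everywhere and are ordered ``(u, v)`` = (column, row);
* the camera frame is +X right, +Y down, +Z forward; the right camera of the
  rectified rig sits at ``+baseline`` along +X of the left camera;
* depth and translation are in millimetres;
* the relative pose ``T_{t+1,t}`` maps frame-``t`` camera coordinates into
  frame-``t+1`` camera coordinates; trajectories store camera-to-world poses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CameraIntrinsics",
    "RelativePose",
    "Trajectory",
    "DepthMap",
    "FlowField",
    "BehindCameraError",
    "InvalidDepthError",
    "project",
    "backproject",
    "depth_from_stereo_flow",
    "se3_exp",
    "se3_log",
    "compose",
    "inverse",
    "identity_pose",
    "translation_pose",
]

# disparity below this many pixels is treated as "at infinity" and masked
DEFAULT_MIN_DISPARITY = 0.1


class BehindCameraError(ValueError):
    """A 3D point with non-positive Z was projected."""


class InvalidDepthError(ValueError):
    """A non-positive or non-finite depth was back-projected."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics of a rectified stereo rig.

    Parameters
    ----------
    fx, fy : float
        Focal lengths in pixels.
    cx, cy : float
        Principal point in pixels.
    width, height : int
        Image size in pixels.
    baseline : float
        Stereo baseline in mm (right camera at +baseline along +X).
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    baseline: float

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.width < 1 or self.height < 1:
            raise ValueError("image size must be at least 1x1")

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of the image grid."""
        return (self.height, self.width)

    def pixel_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (u, v) coordinate arrays of shape (height, width)."""
        v, u = np.mgrid[0 : self.height, 0 : self.width]
        return u.astype(float), v.astype(float)


def _as_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
        raise ValueError("rotation matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("rotation matrix has negative determinant")
    return R


@dataclass(frozen=True)
class RelativePose:
    """A rigid SE(3) transform ``X' = R X + t`` (t in mm).

    Depending on context this is a frame-to-frame relative pose
    (``T_{t+1,t}``: frame-t coordinates to frame-t+1 coordinates) or an
    absolute camera-to-world pose.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _as_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform points of shape (..., 3)."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def matrix34(self) -> np.ndarray:
        """The 3x4 matrix [R | t]."""
        return np.hstack([self.rotation, self.translation[:, None]])


def identity_pose() -> RelativePose:
    return RelativePose(np.eye(3), np.zeros(3))


def translation_pose(tx: float, ty: float = 0.0, tz: float = 0.0) -> RelativePose:
    return RelativePose(np.eye(3), np.array([tx, ty, tz], dtype=float))


def compose(a: RelativePose, b: RelativePose) -> RelativePose:
    """The transform that applies ``b`` first, then ``a``."""
    return RelativePose(a.rotation @ b.rotation, a.rotation @ b.translation + a.translation)


def inverse(a: RelativePose) -> RelativePose:
    Rt = a.rotation.T
    return RelativePose(Rt, -Rt @ a.translation)


def _hat(w: np.ndarray) -> np.ndarray:
    return np.array(
        [[0.0, -w[2], w[1]], [w[2], 0.0, -w[0]], [-w[1], w[0], 0.0]]
    )


def se3_exp(twist: np.ndarray) -> RelativePose:
    """Exponential map from a twist ``(rho, phi)`` (translation part first).

    Uses the closed-form Rodrigues expression with Taylor guards near zero
    rotation; ``se3_exp(0)`` is the identity.
    """
    xi = np.asarray(twist, dtype=float).reshape(6)
    rho, phi = xi[:3], xi[3:]
    theta = np.linalg.norm(phi)
    W = _hat(phi)
    if theta < 1e-10:
        # second-order Taylor expansion; exact enough below the cutoff
        R = np.eye(3) + W + 0.5 * W @ W
        V = np.eye(3) + 0.5 * W + W @ W / 6.0
    else:
        s, c = np.sin(theta), np.cos(theta)
        R = np.eye(3) + (s / theta) * W + ((1.0 - c) / theta**2) * (W @ W)
        V = (
            np.eye(3)
            + ((1.0 - c) / theta**2) * W
            + ((theta - s) / theta**3) * (W @ W)
        )
    # re-orthonormalize to keep the RelativePose invariant at 1e-9 level
    U, _, Vt = np.linalg.svd(R)
    R = U @ np.diag([1.0, 1.0, np.linalg.det(U @ Vt)]) @ Vt
    return RelativePose(R, V @ rho)


def se3_log(pose: RelativePose) -> np.ndarray:
    """Logarithm map; inverse of :func:`se3_exp` for rotation angles < pi."""
    R, t = pose.rotation, pose.translation
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    theta = np.arccos(cos_theta)
    if theta < 1e-10:
        phi = 0.5 * np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        W = _hat(phi)
        V_inv = np.eye(3) - 0.5 * W + W @ W / 12.0
        return np.concatenate([V_inv @ t, phi])
    if np.pi - theta < 1e-6:
        warnings.warn(
            "se3_log near the rotation angle pi: using the symmetric-branch "
            "axis extraction",
            RuntimeWarning,
        )
        # stable branch: axis from the symmetric part R + I
        B = (R + np.eye(3)) / 2.0
        axis = np.sqrt(np.clip(np.diag(B), 0.0, None))
        k = int(np.argmax(axis))
        axis = B[:, k] / max(axis[k], 1e-12)
        axis = axis / np.linalg.norm(axis)
        # fix the sign using the skew part (vanishes exactly at pi)
        skew = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        if np.dot(skew, axis) < 0:
            axis = -axis
        phi = theta * axis
    else:
        phi = (
            theta
            / (2.0 * np.sin(theta))
            * np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        )
    W = _hat(phi)
    half = theta / 2.0
    V_inv = (
        np.eye(3)
        - 0.5 * W
        + (1.0 - half * np.cos(half) / np.sin(half)) / theta**2 * (W @ W)
    )
    return np.concatenate([V_inv @ t, phi])


@dataclass
class Trajectory:
    """An ordered sequence of absolute camera-to-world poses."""

    poses: list[RelativePose]
    timestamps: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.poses) == 0:
            raise ValueError("trajectory must contain at least one pose")
        if self.timestamps is None:
            self.timestamps = np.arange(len(self.poses), dtype=float)
        else:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if len(self.timestamps) != len(self.poses):
                raise ValueError("timestamps and poses must have equal length")

    def __len__(self) -> int:
        return len(self.poses)

    def __getitem__(self, i: int) -> RelativePose:
        return self.poses[i]

    def positions(self) -> np.ndarray:
        """(n, 3) array of camera centers in world coordinates (mm)."""
        return np.array([p.translation for p in self.poses])

    def relative(self, i: int, j: int) -> RelativePose:
        """The transform mapping frame-j camera coords into frame-i coords."""
        return compose(inverse(self.poses[i]), self.poses[j])

    def relative_pose(self, t: int) -> RelativePose:
        """Ground-truth ``P_{t+1,t}``: frame-t coords into frame-t+1 coords."""
        return self.relative(t + 1, t)


@dataclass
class DepthMap:
    """Dense metric depth in mm with a validity mask."""

    depth: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 2:
            raise ValueError("depth must be a 2D grid")
        finite_pos = np.isfinite(self.depth) & (self.depth > 0)
        if self.valid is None:
            self.valid = finite_pos
        else:
            self.valid = np.asarray(self.valid, dtype=bool) & finite_pos

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape


FLOW_KINDS = ("forward-temporal", "backward-temporal", "stereo")


@dataclass
class FlowField:
    """Dense pixel displacement field (du, dv) with a kind tag."""

    flow: np.ndarray
    kind: str = "forward-temporal"

    def __post_init__(self) -> None:
        self.flow = np.asarray(self.flow, dtype=float)
        if self.flow.ndim != 3 or self.flow.shape[2] != 2:
            raise ValueError("flow must have shape (H, W, 2)")
        if self.kind not in FLOW_KINDS:
            raise ValueError(f"unknown flow kind {self.kind!r}")
        if not np.all(np.isfinite(self.flow)):
            raise ValueError("flow must be finite everywhere")

    @property
    def shape(self) -> tuple[int, int]:
        return self.flow.shape[:2]


def project(point3d: np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    """Pinhole projection of points (..., 3) in mm to pixels (..., 2).

    Raises :class:`BehindCameraError` if any Z is non-positive.
    """
    pts = np.asarray(point3d, dtype=float)
    Z = pts[..., 2]
    if np.any(Z <= 0):
        raise BehindCameraError("cannot project a point with non-positive Z")
    u = intr.fx * pts[..., 0] / Z + intr.cx
    v = intr.fy * pts[..., 1] / Z + intr.cy
    return np.stack([u, v], axis=-1)


def backproject(pixel: np.ndarray, depth: np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    """Inverse projection: pixels (..., 2) and depths (...) to 3D points (..., 3)."""
    px = np.asarray(pixel, dtype=float)
    Z = np.asarray(depth, dtype=float)
    if np.any(~np.isfinite(Z)) or np.any(Z <= 0):
        raise InvalidDepthError("depth must be positive and finite")
    X = Z * (px[..., 0] - intr.cx) / intr.fx
    Y = Z * (px[..., 1] - intr.cy) / intr.fy
    return np.stack([X, Y, np.broadcast_to(Z, X.shape)], axis=-1)


def depth_from_stereo_flow(
    stereo_flow: FlowField,
    intr: CameraIntrinsics,
    min_disparity: float = DEFAULT_MIN_DISPARITY,
) -> DepthMap:
    """Convert left-to-right stereo flow into metric depth.

    For a rectified rig with the right camera at +baseline along +X, the
    horizontal flow of a left-image pixel is ``-disparity``; depth is
    ``fx * baseline / disparity``.  Pixels with disparity at or below
    ``min_disparity`` (at or beyond the far cap) are masked invalid rather
    than raised.
    """
    if stereo_flow.kind != "stereo":
        raise ValueError("depth_from_stereo_flow expects a stereo-kind flow")
    disparity = -stereo_flow.flow[..., 0]
    valid = disparity > min_disparity
    depth = np.full(disparity.shape, np.nan)
    depth[valid] = intr.fx * intr.baseline / disparity[valid]
    return DepthMap(depth, valid)
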