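"""Semi-synthetic dynamic stereo sequence generator.

Emulates short endoscopic stereo clips: a rigid textured background surface
observed by a stereo camera with a known trajectory, plus foreground layers
that move rigidly (a "tool" patch driven by a homography sequence) or deform
non-rigidly (a "tissue" patch driven by thin-plate-spline control points).
Sequences are organised into 8 scenarios crossing camera status (S0 moving /
S1 still) with foreground content (tool+tissue / tool / tissue / static).

All geometric ground-truth channels (depth, forward/backward temporal flow,
stereo flow, motion masks) are derived in closed form, not from rendered
images, so they are exact: the reprojection residual of the pose estimator
evaluated at the generating pose vanishes on every rigid pixel.

Textures and patch shapes are procedural (seeded multi-octave harmonic
noise; elongated convex polygon for the tool, smooth Fourier-boundary blob
for the tissue) rather than harvested from real surgical footage — a
deliberate fidelity reduction that keeps generation self-contained.
"""

from __future__ import annotations

import copy
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter1d, map_coordinates
from skimage.draw import polygon as draw_polygon

from . import dataio
from .geometry import (
    CameraIntrinsics,
    DepthMap,
    FlowField,
    RelativePose,
    Trajectory,
    compose,
    identity_pose,
    inverse,
    project,
    se3_exp,
)

__all__ = [
    "ThinPlateSpline",
    "DegenerateControlsError",
    "BackgroundSurface",
    "BackgroundRender",
    "ForegroundLayer",
    "HomographyBounds",
    "HomographySequence",
    "TPSWarpSequence",
    "Scenario",
    "SCENARIOS",
    "StereoSequenceSample",
    "MotionScale",
    "GenerationParams",
    "sample_trajectory",
    "render_background",
    "tps_fit",
    "simulate_tissue_deformation",
    "simulate_tool_motion",
    "make_tool_layer",
    "make_tissue_layer",
    "compose_sequence",
    "generate_sequence",
    "generate_dataset",
    "with_flow_noise",
    "with_depth_noise",
]


# --------------------------------------------------------------------------
# thin-plate splines
# --------------------------------------------------------------------------


class DegenerateControlsError(ValueError):
    """TPS control points are collinear or contain duplicates."""


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log r, written on squared distances with U(0) = 0
    out = np.zeros_like(r2)
    pos = r2 > 0
    out[pos] = 0.5 * r2[pos] * np.log(r2[pos])
    return out


class ThinPlateSpline:
    """2D -> 2D thin-plate-spline warp through control-point pairs.

    Uses the canonical radial kernel ``U(r) = r^2 log r`` with an affine
    polynomial part; kernel weights are constrained orthogonal to the affine
    space via the standard augmented linear system.  With zero
    regularization the warp interpolates the controls exactly and reproduces
    any affine source-to-target relation with identically zero kernel
    weights.
    """

    def __init__(self, src: np.ndarray, dst: np.ndarray, regularization: float = 0.0):
        src = np.asarray(src, dtype=float)
        dst = np.asarray(dst, dtype=float)
        if src.ndim != 2 or src.shape[1] != 2 or src.shape != dst.shape:
            raise ValueError("src and dst must both have shape (n, 2)")
        n = src.shape[0]
        if n < 3:
            raise DegenerateControlsError("need at least 3 control points")
        if regularization < 0:
            raise ValueError("regularization must be >= 0")
        d2 = np.sum((src[:, None, :] - src[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        if d2.min() < 1e-18:
            raise DegenerateControlsError("duplicate control points")
        np.fill_diagonal(d2, 0.0)
        P = np.hstack([np.ones((n, 1)), src])
        if np.linalg.matrix_rank(P, tol=1e-9 * max(1.0, np.abs(src).max())) < 3:
            raise DegenerateControlsError("control points are collinear")
        K = _tps_kernel(d2) + regularization * np.eye(n)
        A = np.zeros((n + 3, n + 3))
        A[:n, :n] = K
        A[:n, n:] = P
        A[n:, :n] = P.T
        b = np.zeros((n + 3, 2))
        b[:n] = dst
        coeffs = np.linalg.solve(A, b)
        self.src = src
        self.dst = dst
        self.kernel_weights = coeffs[:n]  # (n, 2)
        self.affine = coeffs[n:]  # (3, 2): rows are [1, x, y] coefficients

    def __call__(self, query: np.ndarray) -> np.ndarray:
        """Evaluate the warp at query points of shape (..., 2)."""
        q = np.asarray(query, dtype=float)
        flat = q.reshape(-1, 2)
        d2 = np.sum((flat[:, None, :] - self.src[None, :, :]) ** 2, axis=-1)
        U = _tps_kernel(d2)
        out = (
            self.affine[0]
            + flat @ self.affine[1:]
            + U @ self.kernel_weights
        )
        return out.reshape(q.shape)


def tps_fit(src: np.ndarray, dst: np.ndarray, regularization: float = 0.0) -> ThinPlateSpline:
    """Fit a thin-plate-spline warp; see :class:`ThinPlateSpline`."""
    return ThinPlateSpline(src, dst, regularization)


# --------------------------------------------------------------------------
# procedural textures and patch shapes
# --------------------------------------------------------------------------


def _harmonic_texture(rng: np.random.Generator, n_waves: int = 12, octaves: int = 3):
    """A smooth seeded scalar field built from random plane waves.

    Returns a closure mapping points (..., 2) in mm (or px for patch
    textures) to three colour channels in [0, 1].
    """
    freqs, phases, amps = [], [], []
    for o in range(octaves):
        base = 0.15 * 2.0**o  # cycles per unit, coarse -> fine
        ang = rng.uniform(0, 2 * np.pi, size=(3, n_waves))
        mag = base * rng.uniform(0.5, 1.5, size=(3, n_waves))
        freqs.append(np.stack([mag * np.cos(ang), mag * np.sin(ang)], axis=-1))
        phases.append(rng.uniform(0, 2 * np.pi, size=(3, n_waves)))
        amps.append(rng.uniform(0.5, 1.0, size=(3, n_waves)) / 2.0**o)
    freqs = np.concatenate(freqs, axis=1)
    phases = np.concatenate(phases, axis=1)
    amps = np.concatenate(amps, axis=1)
    mean = rng.uniform(0.35, 0.65, size=3)

    def tex(points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        flat = p.reshape(-1, 2)
        out = np.empty((flat.shape[0], 3))
        for c in range(3):
            phase = flat @ freqs[c].T * (2 * np.pi) + phases[c]
            out[:, c] = mean[c] + (np.cos(phase) * amps[c]).sum(axis=1) / (
                2.0 * np.sqrt(amps.shape[1])
            )
        np.clip(out, 0.0, 1.0, out=out)
        return out.reshape(p.shape[:-1] + (3,))

    return tex


def _bilinear(img: np.ndarray, uv: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Bilinearly sample ``img`` (H, W[, C]) at (u, v) points (..., 2)."""
    q = np.asarray(uv, dtype=float)
    flat = q.reshape(-1, 2)
    coords = np.stack([flat[:, 1], flat[:, 0]])  # (row, col)
    if img.ndim == 2:
        out = map_coordinates(img.astype(float), coords, order=1, cval=fill)
        return out.reshape(q.shape[:-1])
    chans = [
        map_coordinates(img[..., c].astype(float), coords, order=1, cval=fill)
        for c in range(img.shape[-1])
    ]
    return np.stack(chans, axis=-1).reshape(q.shape[:-1] + (img.shape[-1],))


# --------------------------------------------------------------------------
# background
# --------------------------------------------------------------------------


@dataclass
class BackgroundSurface:
    """A textured surface in the world frame: a tilted plane with a bowl.

    ``anchor`` is a point on the reference plane (mm), ``normal`` the unit
    normal (pointing toward the camera).  ``bowl_depth`` curves the surface
    into a shallow cavity viewed from inside: at lateral radius
    ``bowl_radius`` from the anchor the surface sits ``bowl_depth`` mm
    nearer the camera (peripheral walls approach, the centre is deepest).
    This gives the scene the depth relief of an endoscopic workspace — and
    keeps the pose problem well-conditioned, since on a pure plane small
    rotations and translations induce nearly indistinguishable flow.  The
    quadric ray intersection is closed-form.  ``height_amplitude`` adds an
    optional smooth harmonic ripple on top (default 0), resolved by
    fixed-point refinement.
    """

    anchor: np.ndarray
    normal: np.ndarray
    texture: object  # callable (..., 2) plane coords -> (..., 3) colours
    bowl_depth: float = 0.0
    bowl_radius: float = 40.0
    height_amplitude: float = 0.0
    height_field: object = None  # callable (..., 2) -> (...) in [-1, 1]

    def __post_init__(self) -> None:
        self.anchor = np.asarray(self.anchor, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        self.normal = n / np.linalg.norm(n)
        # orthonormal in-plane basis for surface coordinates
        a = np.array([1.0, 0.0, 0.0])
        if abs(self.normal @ a) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        e1 = a - (a @ self.normal) * self.normal
        self._e1 = e1 / np.linalg.norm(e1)
        self._e2 = np.cross(self.normal, self._e1)

    @classmethod
    def random(
        cls,
        rng: np.random.Generator,
        depth_mm: float = 60.0,
        tilt_deg: float = 10.0,
        bowl_depth: float = 15.0,
        bowl_radius: float = 40.0,
        height_amplitude: float = 0.0,
    ) -> "BackgroundSurface":
        """A randomly tilted concave surface roughly at ``depth_mm``."""
        tilt = np.deg2rad(rng.uniform(0, tilt_deg))
        az = rng.uniform(0, 2 * np.pi)
        normal = np.array(
            [np.sin(tilt) * np.cos(az), np.sin(tilt) * np.sin(az), -np.cos(tilt)]
        )
        tex = _harmonic_texture(rng)
        hf = None
        if height_amplitude > 0:
            hrng = np.random.default_rng(rng.integers(2**31))
            htex = _harmonic_texture(hrng, n_waves=12, octaves=1)
            hf = lambda p: htex(p * 0.2)[..., 0] * 2.0 - 1.0  # noqa: E731
        bowl = bowl_depth * rng.uniform(0.7, 1.3) if bowl_depth > 0 else 0.0
        return cls(
            anchor=np.array([0.0, 0.0, depth_mm]),
            normal=normal,
            texture=tex,
            bowl_depth=bowl,
            bowl_radius=bowl_radius,
            height_amplitude=height_amplitude,
            height_field=hf,
        )

    def plane_coords(self, points: np.ndarray) -> np.ndarray:
        rel = np.asarray(points, dtype=float) - self.anchor
        return np.stack([rel @ self._e1, rel @ self._e2], axis=-1)

    def _solve_quadric(self, origin: np.ndarray, d: np.ndarray, h: np.ndarray | float):
        """Smallest positive root of the bowl-surface equation along each ray.

        The surface is ``n.(p - anchor) = h + k * rho^2`` with
        ``rho`` the lateral distance from the anchor and
        ``k = bowl_depth / bowl_radius^2`` (positive ``k`` brings the rim
        toward the camera, so every ray from inside the cavity intersects);
        ``h`` is an optional per-ray height offset.
        """
        n = self.normal
        k = -self.bowl_depth / self.bowl_radius**2
        g0 = origin - self.anchor
        nd = d @ n
        ng0 = float(g0 @ n)
        if k == 0.0:
            return (h - ng0) / nd
        A = k * (np.sum(d * d, axis=-1) - nd**2)
        B = 2.0 * k * (d @ g0 - ng0 * nd) + nd
        C = k * (float(g0 @ g0) - ng0**2) + ng0 - h
        disc = B**2 - 4.0 * A * C
        if np.any(disc < 0):
            raise ValueError("ray misses the background surface")
        sq = np.sqrt(disc)
        q = -0.5 * (B + np.where(B >= 0, sq, -sq))
        with np.errstate(divide="ignore", invalid="ignore"):
            r1 = np.where(np.abs(A) > 1e-300, q / A, np.inf)
            r2 = np.where(np.abs(q) > 1e-300, C / q, np.inf)
        roots = np.stack([r1, r2])
        roots = np.where(roots > 0, roots, np.inf)
        s = roots.min(axis=0)
        if np.any(~np.isfinite(s)):
            raise ValueError("background surface behind the camera")
        return s

    def intersect(self, origin: np.ndarray, directions: np.ndarray) -> np.ndarray:
        """Ray parameters s with ``p = origin + s * directions`` on the surface.

        Directions are (..., 3); for camera rays scaled to unit Z the ray
        parameter equals camera-frame depth.  Raises if the surface is not
        in front of the camera for every ray.
        """
        d = np.asarray(directions, dtype=float)
        if np.any(np.abs(d @ self.normal) < 1e-12):
            raise ValueError("ray parallel to background surface")
        s = self._solve_quadric(origin, d, 0.0)
        if self.height_amplitude > 0 and self.height_field is not None:
            for _ in range(40):  # fixed-point refinement onto the ripple field
                p = origin + s[..., None] * d
                h = self.height_amplitude * self.height_field(self.plane_coords(p))
                s = self._solve_quadric(origin, d, h)
        if np.any(s <= 0):
            raise ValueError("background surface behind the camera")
        return s


@dataclass
class BackgroundRender:
    """Per-frame background channels produced by :func:`render_background`."""

    left: list[np.ndarray]
    right: list[np.ndarray]
    depth: list[DepthMap]
    flow_fwd: list[FlowField]
    flow_bwd: list[FlowField]
    flow_stereo: list[FlowField]

    @property
    def n_frames(self) -> int:
        return len(self.left)

    def min_depth(self) -> float:
        return min(float(d.depth[d.valid].min()) for d in self.depth)


def _rigid_flow(
    depth: np.ndarray, pose: RelativePose, intr: CameraIntrinsics
) -> np.ndarray:
    """Closed-form flow induced by a rigid transform at the given depth grid."""
    u, v = intr.pixel_grid()
    px = np.stack([u, v], axis=-1)
    X = np.stack(
        [
            depth * (u - intr.cx) / intr.fx,
            depth * (v - intr.cy) / intr.fy,
            depth,
        ],
        axis=-1,
    )
    Xp = pose.apply(X)
    return project(Xp, intr) - px


def render_background(
    surface: BackgroundSurface, traj: Trajectory, intr: CameraIntrinsics
) -> BackgroundRender:
    """Render the rigid background for every frame of a trajectory.

    Depth is the exact ray-surface intersection; all flow channels are
    computed analytically from depth and the ground-truth poses, so they
    carry no rendering/resampling error.
    """
    u, v = intr.pixel_grid()
    d_cam = np.stack(
        [(u - intr.cx) / intr.fx, (v - intr.cy) / intr.fy, np.ones_like(u)], axis=-1
    )
    lefts, rights, depths, stereos = [], [], [], []
    for pose in traj.poses:
        R, c = pose.rotation, pose.translation
        d_world = d_cam @ R.T
        s = surface.intersect(c, d_world)
        p_world = c + s[..., None] * d_world
        lefts.append(surface.texture(surface.plane_coords(p_world)))
        depths.append(DepthMap(s.copy()))
        stereos.append(
            FlowField(
                np.stack(
                    [-intr.fx * intr.baseline / s, np.zeros_like(s)], axis=-1
                ),
                kind="stereo",
            )
        )
        c_r = c + R @ np.array([intr.baseline, 0.0, 0.0])
        s_r = surface.intersect(c_r, d_world)
        p_world_r = c_r + s_r[..., None] * d_world
        rights.append(surface.texture(surface.plane_coords(p_world_r)))
    fwd, bwd = [], []
    for t in range(len(traj) - 1):
        P = traj.relative_pose(t)  # frame t -> frame t+1
        fwd.append(
            FlowField(_rigid_flow(depths[t].depth, P, intr), kind="forward-temporal")
        )
        bwd.append(
            FlowField(
                _rigid_flow(depths[t + 1].depth, inverse(P), intr),
                kind="backward-temporal",
            )
        )
    return BackgroundRender(lefts, rights, depths, fwd, bwd, stereos)


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MotionScale:
    """Per-frame camera motion bounds: translation in mm, rotation in deg."""

    translation: float = 0.8
    rotation: float = 0.5


def sample_trajectory(
    n_frames: int,
    camera: str,
    motion_scale: MotionScale = MotionScale(),
    seed: int | np.random.Generator = 0,
) -> Trajectory:
    """A smooth random camera trajectory (S0) or a still camera (S1).

    The per-frame incremental twist follows a cubic spline through random
    waypoints, rescaled so every frame-to-frame translation magnitude is at
    most ``motion_scale.translation`` mm and every rotation at most
    ``motion_scale.rotation`` degrees.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if camera not in ("S0", "S1"):
        raise ValueError("camera must be 'S0' or 'S1'")
    if camera == "S1":
        return Trajectory([identity_pose() for _ in range(n_frames)])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    from scipy.interpolate import CubicSpline

    n_way = 4
    way_t = np.linspace(0, n_frames - 1, n_way)
    way = rng.normal(size=(n_way, 6))
    spline = CubicSpline(way_t, way, axis=0)
    deltas = spline(np.arange(n_frames - 1, dtype=float))  # (n-1, 6)
    t_norm = np.linalg.norm(deltas[:, :3], axis=1).max()
    r_norm = np.linalg.norm(deltas[:, 3:], axis=1).max()
    trans_cap = 0.95 * motion_scale.translation
    rot_cap = 0.95 * np.deg2rad(motion_scale.rotation)
    if t_norm > 0:
        deltas[:, :3] *= trans_cap / t_norm
    if r_norm > 0:
        deltas[:, 3:] *= rot_cap / r_norm
    poses = [identity_pose()]
    for d in deltas:
        poses.append(compose(poses[-1], se3_exp(d)))
    return Trajectory(poses)


# --------------------------------------------------------------------------
# foreground motion models
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class HomographyBounds:
    """Bounds on the random target homography of a tool patch.

    The bounds describe the excursion reached over ``reference_frames``
    frames; shorter sequences traverse proportionally less, so the tool's
    image-space velocity is independent of the sequence length.
    """

    rotation_deg: float = 15.0
    translation_px: float = 60.0
    scale: float = 0.15
    perspective: float = 2e-4
    reference_frames: int = 30


@dataclass
class HomographySequence:
    """Per-frame normalized 3x3 homographies in layer-local coordinates."""

    matrices: np.ndarray  # (n_frames, 3, 3), frame 0 = identity, h33 = 1

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[1:] != (3, 3):
            raise ValueError("matrices must have shape (n, 3, 3)")
        if not np.allclose(self.matrices[0], np.eye(3), atol=1e-12):
            raise ValueError("frame-0 homography must be the identity")
        self.matrices = self.matrices / self.matrices[:, 2:3, 2:3]

    @property
    def n_frames(self) -> int:
        return self.matrices.shape[0]

    def warp(self, t: int, q: np.ndarray) -> np.ndarray:
        return _apply_homography(self.matrices[t], q)

    def inverse_warp(self, t: int, x: np.ndarray) -> np.ndarray:
        return _apply_homography(np.linalg.inv(self.matrices[t]), x)


def _apply_homography(H: np.ndarray, pts: np.ndarray) -> np.ndarray:
    p = np.asarray(pts, dtype=float)
    flat = p.reshape(-1, 2)
    homog = np.hstack([flat, np.ones((flat.shape[0], 1))]) @ H.T
    return (homog[:, :2] / homog[:, 2:3]).reshape(p.shape)


@dataclass
class TPSWarpSequence:
    """Per-frame thin-plate-spline warps in layer-local coordinates.

    ``sources`` is the fixed control grid, ``targets`` the per-frame control
    positions (frame 0 equals the sources: identity warp).  Forward and
    backward splines are fitted lazily per frame; the backward spline is the
    interpolating warp targets -> sources used for inverse warping.
    """

    sources: np.ndarray  # (m, 2)
    targets: np.ndarray  # (n_frames, m, 2)
    max_displacement: float = np.inf

    def __post_init__(self) -> None:
        self.sources = np.asarray(self.sources, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if not np.allclose(self.targets[0], self.sources, atol=1e-12):
            raise ValueError("frame-0 targets must equal the sources")
        self._fwd: dict[int, ThinPlateSpline] = {}
        self._bwd: dict[int, ThinPlateSpline] = {}

    @property
    def n_frames(self) -> int:
        return self.targets.shape[0]

    def _is_identity(self, t: int) -> bool:
        return bool(np.allclose(self.targets[t], self.sources, atol=1e-12))

    def spline(self, t: int) -> ThinPlateSpline:
        if t not in self._fwd:
            self._fwd[t] = ThinPlateSpline(self.sources, self.targets[t])
        return self._fwd[t]

    def warp(self, t: int, q: np.ndarray) -> np.ndarray:
        if self._is_identity(t):
            return np.asarray(q, dtype=float).copy()
        return self.spline(t)(q)

    def inverse_warp(self, t: int, x: np.ndarray) -> np.ndarray:
        if self._is_identity(t):
            return np.asarray(x, dtype=float).copy()
        if t not in self._bwd:
            self._bwd[t] = ThinPlateSpline(self.targets[t], self.sources)
        return self._bwd[t](x)


def simulate_tool_motion(
    layer: "ForegroundLayer",
    n_frames: int,
    bounds: HomographyBounds = HomographyBounds(),
    seed: int | np.random.Generator = 0,
) -> HomographySequence:
    """Smoothly interpolate from identity toward a random in-bounds homography.

    Rotation/scale/perspective act about the layer centre; the easing is a
    smoothstep so the patch accelerates and decelerates like a handled
    instrument.
    """
    if layer.category != "tool":
        raise ValueError("tool motion applies to tool layers")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    span = min(1.0, (n_frames - 1) / max(1, bounds.reference_frames - 1))
    theta = span * np.deg2rad(rng.uniform(-bounds.rotation_deg, bounds.rotation_deg))
    tx, ty = span * rng.uniform(-bounds.translation_px, bounds.translation_px, size=2)
    sc = 1.0 + span * rng.uniform(-bounds.scale, bounds.scale)
    p1, p2 = span * rng.uniform(-bounds.perspective, bounds.perspective, size=2)
    cx, cy = layer.center
    mats = np.empty((n_frames, 3, 3))
    for t in range(n_frames):
        tau = t / (n_frames - 1) if n_frames > 1 else 0.0
        e = tau * tau * (3.0 - 2.0 * tau)  # smoothstep easing
        th, s = e * theta, 1.0 + e * (sc - 1.0)
        core = np.array(
            [
                [s * np.cos(th), -s * np.sin(th), e * tx],
                [s * np.sin(th), s * np.cos(th), e * ty],
                [e * p1, e * p2, 1.0],
            ]
        )
        Tc = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1]], dtype=float)
        Tc_inv = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1]], dtype=float)
        mats[t] = Tc @ core @ Tc_inv
    mats[0] = np.eye(3)
    return HomographySequence(mats)


def simulate_tissue_deformation(
    layer: "ForegroundLayer",
    n_frames: int,
    max_disp: float = 10.0,
    n_controls: int = 5,
    seed: int | np.random.Generator = 0,
    step_sigma: float = 3.0,
    smooth_sigma: float = 1.5,
) -> TPSWarpSequence:
    """Smooth bounded random walks of a TPS control grid over the patch.

    Raw Gaussian steps are smoothed along time (so the deformation is
    temporally coherent), rescaled to keep the per-frame RMS control step at
    ``step_sigma`` px, accumulated, and clipped so no control strays more
    than ``max_disp`` px from its source.
    """
    if layer.category != "tissue":
        raise ValueError("tissue deformation applies to tissue layers")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = layer.alpha.shape
    gx = np.linspace(0, w - 1, n_controls)
    gy = np.linspace(0, h - 1, n_controls)
    src = np.stack(np.meshgrid(gx, gy), axis=-1).reshape(-1, 2)
    m = src.shape[0]
    disp = np.zeros((n_frames, m, 2))
    if max_disp > 0 and n_frames > 1:
        steps = rng.normal(size=(n_frames - 1, m, 2))
        if smooth_sigma > 0 and n_frames > 2:
            steps = gaussian_filter1d(steps, smooth_sigma, axis=0, mode="nearest")
        rms = np.sqrt(np.mean(steps**2))
        if rms > 0:
            steps *= step_sigma / np.sqrt(2.0) / rms  # per-step 2D RMS = step_sigma
        disp[1:] = np.cumsum(steps, axis=0)
        norms = np.linalg.norm(disp, axis=-1, keepdims=True)
        over = norms > max_disp
        scale = np.where(over, max_disp / np.maximum(norms, 1e-12), 1.0)
        disp *= scale
    return TPSWarpSequence(src, src[None] + disp, max_displacement=max_disp)


# --------------------------------------------------------------------------
# foreground layers
# --------------------------------------------------------------------------


@dataclass
class ForegroundLayer:
    """A textured alpha-masked patch composited over the background.

    The patch lives on a local pixel grid; ``anchor`` places the local
    centre in the frame-0 left image.  ``depth`` is the constant layer depth
    in mm (assigned at composition; must be nearer than the background).
    The intrinsic motion model is a :class:`HomographySequence` (tool) or a
    :class:`TPSWarpSequence` (tissue); ``moving`` distinguishes animated
    layers from geometrically static overlays.
    """

    texture: np.ndarray  # (h, w, 3) in [0, 1]
    alpha: np.ndarray  # (h, w) bool
    anchor: tuple[float, float]  # (u, v) in the frame-0 left image
    category: str  # "tool" | "tissue"
    depth: float | None = None
    motion: HomographySequence | TPSWarpSequence | None = None
    moving: bool = False

    def __post_init__(self) -> None:
        if self.category not in ("tool", "tissue"):
            raise ValueError("category must be 'tool' or 'tissue'")
        self.alpha = np.asarray(self.alpha, dtype=bool)
        if self.moving and self.motion is None:
            raise ValueError("a moving layer needs a motion model")

    @property
    def center(self) -> tuple[float, float]:
        h, w = self.alpha.shape
        return ((w - 1) / 2.0, (h - 1) / 2.0)

    def warp(self, t: int, q: np.ndarray) -> np.ndarray:
        if self.motion is None:
            return np.asarray(q, dtype=float).copy()
        return self.motion.warp(t, q)

    def inverse_warp(self, t: int, x: np.ndarray) -> np.ndarray:
        if self.motion is None:
            return np.asarray(x, dtype=float).copy()
        return self.motion.inverse_warp(t, x)


def make_tissue_layer(
    intr: CameraIntrinsics,
    rng: np.random.Generator,
    coverage: float = 0.20,
    anchor: tuple[float, float] | None = None,
) -> ForegroundLayer:
    """A smooth random blob patch sized to cover ~``coverage`` of the frame."""
    area = coverage * intr.width * intr.height
    r0 = float(np.sqrt(area / np.pi))
    theta = np.linspace(0, 2 * np.pi, 180, endpoint=False)
    r = r0 * np.ones_like(theta)
    for k in range(2, 6):
        r += r0 * rng.uniform(0.02, 0.10) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    pad = 8
    size = int(np.ceil(2 * r.max())) + 2 * pad
    cx = cy = (size - 1) / 2.0
    rows = cy + r * np.sin(theta)
    cols = cx + r * np.cos(theta)
    alpha = np.zeros((size, size), dtype=bool)
    rr, cc = draw_polygon(rows, cols, shape=alpha.shape)
    alpha[rr, cc] = True
    tex = _harmonic_texture(rng)(
        np.stack(np.meshgrid(np.arange(size), np.arange(size)), axis=-1) * 0.08
    )
    if anchor is None:
        anchor = (
            rng.uniform(0.3, 0.7) * intr.width,
            rng.uniform(0.3, 0.7) * intr.height,
        )
    return ForegroundLayer(tex, alpha, anchor, "tissue")


def make_tool_layer(
    intr: CameraIntrinsics,
    rng: np.random.Generator,
    coverage: float = 0.12,
    anchor: tuple[float, float] | None = None,
) -> ForegroundLayer:
    """An elongated convex polygon patch (instrument-shaft silhouette)."""
    area = coverage * intr.width * intr.height
    aspect = rng.uniform(3.0, 5.0)
    width = float(np.sqrt(area / aspect))
    length = aspect * width
    ang = rng.uniform(0, np.pi)
    taper = rng.uniform(0.5, 0.9)
    half = np.array(
        [
            [-length / 2, -width / 2],
            [length / 2, -taper * width / 2],
            [length / 2, taper * width / 2],
            [-length / 2, width / 2],
        ]
    )
    R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    corners = half @ R.T
    pad = 6
    ext = corners.max(axis=0) - corners.min(axis=0)
    size_w = int(np.ceil(ext[0])) + 2 * pad
    size_h = int(np.ceil(ext[1])) + 2 * pad
    center = np.array([(size_w - 1) / 2.0, (size_h - 1) / 2.0])
    pts = corners + center
    alpha = np.zeros((size_h, size_w), dtype=bool)
    rr, cc = draw_polygon(pts[:, 1], pts[:, 0], shape=alpha.shape)
    alpha[rr, cc] = True
    grid = np.stack(np.meshgrid(np.arange(size_w), np.arange(size_h)), axis=-1)
    tex = _harmonic_texture(rng)(grid * 0.15)
    tex = 0.3 * tex + 0.5  # metallic: low-contrast, bright
    if anchor is None:
        anchor = (
            rng.uniform(0.3, 0.7) * intr.width,
            rng.uniform(0.3, 0.7) * intr.height,
        )
    return ForegroundLayer(tex, alpha, anchor, "tool")


# --------------------------------------------------------------------------
# scenarios
# --------------------------------------------------------------------------

_CONTENTS = ("tool+tissue", "tool", "tissue", "static")


@dataclass(frozen=True)
class Scenario:
    """Camera status (S0 moving / S1 still) x moving foreground content."""

    camera: str
    content: str

    def __post_init__(self) -> None:
        if self.camera not in ("S0", "S1"):
            raise ValueError("camera must be 'S0' or 'S1'")
        if self.content not in _CONTENTS:
            raise ValueError(f"content must be one of {_CONTENTS}")

    @property
    def name(self) -> str:
        return f"{self.camera}-{self.content.replace('+', '-')}"

    @classmethod
    def from_name(cls, name: str) -> "Scenario":
        cam, _, rest = name.partition("-")
        content = rest.replace("tool-tissue", "tool+tissue")
        return cls(cam, content)


SCENARIOS = tuple(
    Scenario(cam, content) for cam in ("S0", "S1") for content in _CONTENTS
)


# --------------------------------------------------------------------------
# composition
# --------------------------------------------------------------------------


@dataclass
class StereoSequenceSample:
    """One generated sequence with all ground-truth channels.

    Temporal flow fields are indexed by frame pair: ``flow_fwd[t]`` lives on
    frame ``t`` and points to ``t+1``; ``flow_bwd[t]`` lives on frame
    ``t+1`` and points back to ``t``.
    """

    left: list[np.ndarray]
    right: list[np.ndarray]
    depth: list[DepthMap]
    flow_fwd: list[FlowField]
    flow_bwd: list[FlowField]
    flow_stereo: list[FlowField]
    motion_mask: list[np.ndarray]
    intrinsics: CameraIntrinsics
    trajectory: Trajectory
    scenario: Scenario
    seed: int | None = None
    layer_support: list[np.ndarray] = field(default_factory=list)
    moving_support: list[np.ndarray] = field(default_factory=list)
    # per-frame max intrinsic (non-rigid) displacement over moving layers, px
    intrinsic_disp: list[np.ndarray] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.left)

    def relative_pose(self, t: int) -> RelativePose:
        return self.trajectory.relative_pose(t)


def _anchoring_homography(
    pose: RelativePose, depth: float, intr: CameraIntrinsics
) -> np.ndarray:
    """Image homography induced by a rigid pose on the plane z = depth.

    Exactly reproduces ``x -> project(pose * backproject(x, depth))``; used
    to advect non-moving layers so "static foreground" stays geometrically
    consistent under a moving camera.
    """
    K = np.array(
        [[intr.fx, 0, intr.cx], [0, intr.fy, intr.cy], [0, 0, 1]], dtype=float
    )
    K_inv = np.linalg.inv(K)
    n = np.array([0.0, 0.0, 1.0])
    H = K @ (pose.rotation + np.outer(pose.translation, n) / depth) @ K_inv
    return H / H[2, 2]


MASK_DISPLACEMENT_THRESHOLD = 0.1  # px of intrinsic motion that counts as "moving"


def compose_sequence(
    background: BackgroundRender,
    layers: list[ForegroundLayer],
    traj: Trajectory,
    intr: CameraIntrinsics,
    scenario: Scenario | None = None,
    seed: int | None = None,
) -> StereoSequenceSample:
    """Layer foreground patches over a rendered background.

    Composition is back-to-front: background, tissue layers, then tool
    layers (tools occlude tissue).  A layer's placement at frame ``t`` is
    the composition of (i) the accumulated camera-induced plane homography
    at the layer's depth (scene anchoring) and (ii) its intrinsic warp in
    local coordinates.  Ground-truth channels on the layer support are
    overridden analytically: depth with the layer depth, stereo flow with
    the layer disparity, temporal flow with anchoring + intrinsic
    displacement.  The motion mask is the union, over layers flagged
    moving, of pixels whose intrinsic displacement in the frame pair
    exceeds 0.1 px.
    """
    n = background.n_frames
    if len(traj) != n:
        raise ValueError("trajectory and background frame counts differ")
    if scenario is None:
        scenario = Scenario("S0", "static")
    min_bg = background.min_depth()
    ordered = [l for l in layers if l.category == "tissue"] + [
        l for l in layers if l.category == "tool"
    ]
    for layer in ordered:
        if layer.depth is None or not (0 < layer.depth < min_bg):
            raise ValueError(
                "every layer must have a depth strictly nearer than the background"
            )

    left = [img.copy() for img in background.left]
    right = [img.copy() for img in background.right]
    depth = [DepthMap(d.depth.copy(), d.valid.copy()) for d in background.depth]
    flow_fwd = [FlowField(f.flow.copy(), f.kind) for f in background.flow_fwd]
    flow_bwd = [FlowField(f.flow.copy(), f.kind) for f in background.flow_bwd]
    flow_stereo = [FlowField(f.flow.copy(), f.kind) for f in background.flow_stereo]
    h_img, w_img = intr.shape
    masks = [np.zeros((h_img, w_img), dtype=bool) for _ in range(n)]
    supports = [np.zeros((h_img, w_img), dtype=bool) for _ in range(n)]
    moving_supports = [np.zeros((h_img, w_img), dtype=bool) for _ in range(n)]
    intrinsic_disps = [np.zeros((h_img, w_img)) for _ in range(n)]

    u, v = intr.pixel_grid()
    grid = np.stack([u, v], axis=-1)  # (H, W, 2)

    for layer in ordered:
        d_l = float(layer.depth)
        disparity = intr.fx * intr.baseline / d_l
        offset = np.array(layer.anchor) - np.array(layer.center)
        A = [np.eye(3)]
        for t in range(n - 1):
            H_t = _anchoring_homography(traj.relative_pose(t), d_l, intr)
            A.append(H_t @ A[-1])
        h_l, w_l = layer.alpha.shape

        def local_coords(t: int, pix: np.ndarray) -> np.ndarray:
            y = _apply_homography(np.linalg.inv(A[t]), pix)
            return layer.inverse_warp(t, y - offset)

        def support_of(q: np.ndarray) -> np.ndarray:
            inb = (
                (q[..., 0] >= 0)
                & (q[..., 0] <= w_l - 1)
                & (q[..., 1] >= 0)
                & (q[..., 1] <= h_l - 1)
            )
            a = _bilinear(layer.alpha.astype(float), q, fill=0.0)
            return inb & (a >= 0.5)

        for t in range(n):
            q = local_coords(t, grid)
            sup = support_of(q)
            if not sup.any():
                continue
            qs = q[sup]
            left[t][sup] = _bilinear(layer.texture, qs)
            depth[t].depth[sup] = d_l
            depth[t].valid[sup] = True
            flow_stereo[t].flow[sup] = [-disparity, 0.0]
            supports[t] |= sup
            if layer.moving:
                moving_supports[t] |= sup

            # intrinsic displacement for the frame pair at t (last frame
            # falls back to the preceding pair)
            ta, tb = (t, t + 1) if t < n - 1 else (t - 1, t)
            d_int = np.linalg.norm(layer.warp(tb, qs) - layer.warp(ta, qs), axis=-1)
            if layer.moving:
                m = np.zeros_like(sup)
                m[sup] = d_int > MASK_DISPLACEMENT_THRESHOLD
                masks[t] |= m
                intrinsic_disps[t][sup] = np.maximum(intrinsic_disps[t][sup], d_int)

            if t < n - 1:
                x_next = _apply_homography(A[t + 1], layer.warp(t + 1, qs) + offset)
                flow_fwd[t].flow[sup] = x_next - grid[sup]
            if t > 0:
                x_prev = _apply_homography(A[t - 1], layer.warp(t - 1, qs) + offset)
                flow_bwd[t - 1].flow[sup] = x_prev - grid[sup]

            # right image: the layer appears shifted left by its disparity
            q_r = local_coords(t, grid + [disparity, 0.0])
            sup_r = support_of(q_r)
            if sup_r.any():
                right[t][sup_r] = _bilinear(layer.texture, q_r[sup_r])

    return StereoSequenceSample(
        left=left,
        right=right,
        depth=depth,
        flow_fwd=flow_fwd,
        flow_bwd=flow_bwd,
        flow_stereo=flow_stereo,
        motion_mask=masks,
        intrinsics=intr,
        trajectory=traj,
        scenario=scenario,
        seed=seed,
        layer_support=supports,
        moving_support=moving_supports,
        intrinsic_disp=intrinsic_disps,
    )


# --------------------------------------------------------------------------
# end-to-end generation
# --------------------------------------------------------------------------


def default_intrinsics() -> CameraIntrinsics:
    """Default rig: a 192x144 endoscope-like camera (~62 deg horizontal FOV)."""
    return CameraIntrinsics(
        fx=160.0, fy=160.0, cx=95.5, cy=71.5, width=192, height=144, baseline=4.2
    )


@dataclass(frozen=True)
class GenerationParams:
    """Tunable generator defaults, all overridable per call."""

    background_depth: float = 60.0  # mm, nominal surface distance
    background_tilt: float = 10.0  # deg, max random surface tilt
    bowl_depth: float = 15.0  # mm, cavity relief at bowl_radius
    bowl_radius: float = 40.0  # mm
    height_amplitude: float = 0.0  # mm, extra harmonic ripple (0 = smooth bowl)
    motion_scale: MotionScale = MotionScale()  # S0 per-frame camera motion caps
    tissue_coverage: float = 0.20  # fraction of frame area
    tool_coverage: float = 0.12
    tissue_max_disp: float = 14.0  # px, control-point excursion cap
    tissue_step_sigma: float = 5.0  # px, per-frame RMS control step
    tissue_controls: int = 5  # control grid is n x n
    tool_bounds: HomographyBounds = HomographyBounds()
    layer_depth_range: tuple[float, float] = (0.5, 0.8)  # x min background depth


def generate_sequence(
    scenario: Scenario | str,
    n_frames: int = 30,
    seed: int = 0,
    intr: CameraIntrinsics | None = None,
    params: GenerationParams = GenerationParams(),
) -> StereoSequenceSample:
    """Generate one complete sequence for a scenario, deterministically."""
    if isinstance(scenario, str):
        scenario = Scenario.from_name(scenario)
    if intr is None:
        intr = default_intrinsics()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    surface = BackgroundSurface.random(
        rng,
        depth_mm=params.background_depth,
        tilt_deg=params.background_tilt,
        bowl_depth=params.bowl_depth,
        bowl_radius=params.bowl_radius,
        height_amplitude=params.height_amplitude,
    )
    traj = sample_trajectory(n_frames, scenario.camera, params.motion_scale, rng)
    bg = render_background(surface, traj, intr)
    min_bg = bg.min_depth()
    layers: list[ForegroundLayer] = []
    lo, hi = params.layer_depth_range
    if scenario.content in ("tissue", "tool+tissue"):
        layer = make_tissue_layer(intr, rng, coverage=params.tissue_coverage)
        layer.depth = float(rng.uniform(lo, hi) * min_bg)
        layer.motion = simulate_tissue_deformation(
            layer,
            n_frames,
            max_disp=params.tissue_max_disp,
            n_controls=params.tissue_controls,
            seed=rng,
            step_sigma=params.tissue_step_sigma,
        )
        layer.moving = True
        layers.append(layer)
    if scenario.content in ("tool", "tool+tissue"):
        layer = make_tool_layer(intr, rng, coverage=params.tool_coverage)
        layer.depth = float(rng.uniform(lo, hi) * min_bg)
        layer.motion = simulate_tool_motion(
            layer, n_frames, bounds=params.tool_bounds, seed=rng
        )
        layer.moving = True
        layers.append(layer)
    return compose_sequence(bg, layers, traj, intr, scenario=scenario, seed=seed)


def with_flow_noise(
    sample: StereoSequenceSample, sigma: float, rng: np.random.Generator
) -> StereoSequenceSample:
    """A copy of the sample with iid Gaussian noise on the temporal flows."""
    out = copy.copy(sample)
    out.flow_fwd = [
        FlowField(f.flow + rng.normal(0, sigma, f.flow.shape), f.kind)
        for f in sample.flow_fwd
    ]
    out.flow_bwd = [
        FlowField(f.flow + rng.normal(0, sigma, f.flow.shape), f.kind)
        for f in sample.flow_bwd
    ]
    return out


def with_depth_noise(
    sample: StereoSequenceSample, frac: float, rng: np.random.Generator
) -> StereoSequenceSample:
    """A copy with multiplicative Gaussian depth noise (e.g. frac=0.02 = 2%)."""
    out = copy.copy(sample)
    out.depth = [
        DepthMap(d.depth * (1.0 + frac * rng.normal(size=d.depth.shape)), d.valid.copy())
        for d in sample.depth
    ]
    return out


# --------------------------------------------------------------------------
# dataset on disk
# --------------------------------------------------------------------------

DEPTH_PNG_SCALE = 0.01  # mm per 16-bit count: max representable depth 655 mm


def write_sequence(out_dir: str | os.PathLike, sample: StereoSequenceSample) -> None:
    """Write one sequence in the standard directory layout."""
    out = Path(out_dir)
    for sub in ("left", "right", "depth", "flow_fwd", "flow_bwd", "flow_stereo", "mask"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    import imageio.v3 as iio

    n = sample.n_frames
    for t in range(n):
        name = f"{t:06d}"
        iio.imwrite(
            out / "left" / f"{name}.png",
            np.round(sample.left[t] * 255).astype(np.uint8),
        )
        iio.imwrite(
            out / "right" / f"{name}.png",
            np.round(sample.right[t] * 255).astype(np.uint8),
        )
        dataio.write_depth_png(
            out / "depth" / f"{name}.png", sample.depth[t].depth, DEPTH_PNG_SCALE
        )
        dataio.write_flo(out / "flow_stereo" / f"{name}.flo", sample.flow_stereo[t])
        iio.imwrite(
            out / "mask" / f"{name}.png",
            (sample.motion_mask[t].astype(np.uint8)) * 255,
        )
        if t < n - 1:
            dataio.write_flo(out / "flow_fwd" / f"{name}.flo", sample.flow_fwd[t])
            dataio.write_flo(out / "flow_bwd" / f"{name}.flo", sample.flow_bwd[t])
    dataio.write_tum(out / "traj_gt.tum", sample.trajectory)
    dataio.write_intrinsics(out / "intrinsics.yaml", sample.intrinsics)
    meta = {
        "scenario": sample.scenario.name,
        "seed": sample.seed,
        "n_frames": n,
        "depth_scale_mm": DEPTH_PNG_SCALE,
    }
    with open(out / "meta.yaml", "w") as f:
        yaml.safe_dump(meta, f, sort_keys=True)


def read_sequence(seq_dir: str | os.PathLike) -> StereoSequenceSample:
    """Load a sequence previously written by :func:`write_sequence`."""
    import imageio.v3 as iio

    seq = Path(seq_dir)
    with open(seq / "meta.yaml") as f:
        meta = yaml.safe_load(f)
    intr = dataio.read_intrinsics(seq / "intrinsics.yaml")
    traj = dataio.read_tum(seq / "traj_gt.tum")
    n = meta["n_frames"]
    scale = meta.get("depth_scale_mm", DEPTH_PNG_SCALE)
    left, right, depth, stereo, mask = [], [], [], [], []
    fwd, bwd = [], []
    for t in range(n):
        name = f"{t:06d}"
        left.append(iio.imread(seq / "left" / f"{name}.png").astype(float) / 255.0)
        right.append(iio.imread(seq / "right" / f"{name}.png").astype(float) / 255.0)
        depth.append(DepthMap(dataio.read_depth_png(seq / "depth" / f"{name}.png", scale)))
        stereo.append(dataio.read_flo(seq / "flow_stereo" / f"{name}.flo", "stereo"))
        mask.append(iio.imread(seq / "mask" / f"{name}.png") > 127)
        if t < n - 1:
            fwd.append(dataio.read_flo(seq / "flow_fwd" / f"{name}.flo", "forward-temporal"))
            bwd.append(dataio.read_flo(seq / "flow_bwd" / f"{name}.flo", "backward-temporal"))
    return StereoSequenceSample(
        left=left,
        right=right,
        depth=depth,
        flow_fwd=fwd,
        flow_bwd=bwd,
        flow_stereo=stereo,
        motion_mask=mask,
        intrinsics=intr,
        trajectory=traj,
        scenario=Scenario.from_name(meta["scenario"]),
        seed=meta.get("seed"),
    )


def sequence_seed(master_seed: int, index: int) -> int:
    """Derive an independent per-sequence seed from (master seed, index)."""
    return int(
        np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0]
        % (2**31)
    )


def generate_dataset(
    out_dir: str | os.PathLike,
    scenarios: list[Scenario | str] | None = None,
    n_sequences: int = 8,
    n_frames: int = 30,
    seed: int = 0,
    intr: CameraIntrinsics | None = None,
    params: GenerationParams = GenerationParams(),
) -> dict:
    """Generate ``n_sequences`` sequences cycling through a scenario mix.

    Writes the directory layout plus a ``manifest.yaml`` recording seeds and
    parameters; regeneration with the same master seed is byte-identical
    for the array channels.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames per sequence")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if scenarios is None:
        scenarios = list(SCENARIOS)
    scenarios = [s if isinstance(s, Scenario) else Scenario.from_name(s) for s in scenarios]
    entries = []
    for i in range(n_sequences):
        scenario = scenarios[i % len(scenarios)]
        seq_seed = sequence_seed(seed, i)
        sample = generate_sequence(scenario, n_frames, seq_seed, intr, params)
        name = f"seq_{i:04d}_{scenario.name}"
        write_sequence(out / name, sample)
        entries.append(
            {
                "name": name,
                "scenario": scenario.name,
                "seed": seq_seed,
                "n_frames": n_frames,
            }
        )
    manifest = {"master_seed": seed, "sequences": entries}
    with open(out / "manifest.yaml", "w") as f:
        yaml.safe_dump(manifest, f, sort_keys=True)
    return manifest
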