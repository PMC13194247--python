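"""Weighted dense relative-pose estimation.

The central model: given dense temporal data association (forward flow),
metric depth and a per-pixel weight map ``W = 1 - M``, estimate the SE(3)
relative pose ``T_{t+1,t}`` minimizing the weighted sum of squared
residuals

    sum_{x in Omega}  W(x) * r(T, x)^2

where ``r`` is the normalized reprojection residual

    r(T, x) = sqrt(1/(H*W)) * || pi(T pi^{-1}(D_t(x), x)) - (x + F_fwd(x)) ||

(or, as an ablation, a 3D point-alignment residual in mm).  The
minimization runs damped Gauss-Newton (Levenberg-Marquardt) on the 6-dim
twist with a left-multiplicative update, initialized at the identity, with
a 30-iteration cap by default.

The estimator follows a model/results idiom: build a
:class:`RelativePoseModel` from the per-frame-pair grids, call
:meth:`~RelativePoseModel.fit`, and read the estimate, diagnostics and
``summary()`` off the returned :class:`RelativePoseResults`, which also
exposes the weighted-inlier / vanilla refinement passes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import (
    CameraIntrinsics,
    DepthMap,
    FlowField,
    RelativePose,
    Trajectory,
    compose,
    identity_pose,
    inverse,
    se3_exp,
)
from .motion import WeightMap, constant_weight

__all__ = [
    "ResidualOptions",
    "DegenerateProblemError",
    "RelativePoseModel",
    "RelativePoseResults",
    "estimate_pose",
    "refine_pose",
    "chain_poses",
    "pose_l1_loss",
]


class DegenerateProblemError(ValueError):
    """Too few usable pixels / zero total weight: no rigid anchor to pose on."""


@dataclass(frozen=True)
class ResidualOptions:
    """Optimizer and residual configuration.

    ``residual`` selects the 2D reprojection residual (default) or the 3D
    point-alignment ablation.  The Levenberg-Marquardt damping starts at
    ``lm_lambda0``, multiplies by ``lm_factor`` on a rejected step and
    divides by it on acceptance; iteration stops at ``max_iterations`` or
    when the twist update norm falls below ``tol``.  ``huber_delta``
    (normalized residual units) switches on an optional Huber kernel, off
    by default.  ``stride`` subsamples the pixel grid for speed (1 = dense).
    """

    residual: str = "reprojection-2d"  # or "alignment-3d"
    max_iterations: int = 30
    tol: float = 1e-8
    lm_lambda0: float = 1e-4
    lm_factor: float = 10.0
    huber_delta: float | None = None
    stride: int = 1
    jacobian: str = "analytic"  # or "numeric" (finite differences, testing)

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.residual not in ("reprojection-2d", "alignment-3d"):
            raise ValueError("residual must be 'reprojection-2d' or 'alignment-3d'")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


def _hat_batch(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    H = np.zeros((n, 3, 3))
    H[:, 0, 1], H[:, 0, 2] = -X[:, 2], X[:, 1]
    H[:, 1, 0], H[:, 1, 2] = X[:, 2], -X[:, 0]
    H[:, 2, 0], H[:, 2, 1] = -X[:, 1], X[:, 0]
    return H


class RelativePoseModel:
    """Dense weighted SE(3) relative-pose model for one frame pair.

    Parameters
    ----------
    flow_fwd : FlowField
        Forward temporal flow on frame t (data association to frame t+1).
    depth_t : DepthMap
        Metric depth of frame t in mm.
    intrinsics : CameraIntrinsics
        Pinhole intrinsics shared by both frames.
    weights : WeightMap, optional
        Per-pixel weights in [0, 1]; defaults to all ones (unweighted).
    depth_t1 : DepthMap, optional
        Depth of frame t+1; required for the 3D-alignment residual.
    options : ResidualOptions, optional
    """

    def __init__(
        self,
        flow_fwd: FlowField,
        depth_t: DepthMap,
        intrinsics: CameraIntrinsics,
        weights: WeightMap | None = None,
        depth_t1: DepthMap | None = None,
        options: ResidualOptions | None = None,
    ):
        self.options = options or ResidualOptions()
        self.intrinsics = intrinsics
        h, w = depth_t.shape
        if flow_fwd.shape != (h, w):
            raise ValueError("flow and depth grids must share a shape")
        if weights is None:
            weights = constant_weight((h, w))
        if weights.shape != (h, w):
            raise ValueError("weight map shape mismatch with the residual grid")
        if self.options.residual == "alignment-3d" and depth_t1 is None:
            raise ValueError("the 3D-alignment residual requires depth_t1")
        self.flow_fwd = flow_fwd
        self.depth_t = depth_t
        self.depth_t1 = depth_t1
        self.weights = weights
        self._norm = np.sqrt(1.0 / (h * w))
        self._prepare()

    # -- static problem setup ------------------------------------------------

    def _prepare(self) -> None:
        intr = self.intrinsics
        h, w = self.depth_t.shape
        u, v = intr.pixel_grid()
        sel = self.depth_t.valid.copy()
        if self.options.stride > 1:
            stride_mask = np.zeros_like(sel)
            stride_mask[:: self.options.stride, :: self.options.stride] = True
            sel &= stride_mask
        target = np.stack([u, v], axis=-1) + self.flow_fwd.flow
        sel &= (
            (target[..., 0] >= 0)
            & (target[..., 0] <= w - 1)
            & (target[..., 1] >= 0)
            & (target[..., 1] <= h - 1)
        )
        if self.options.residual == "alignment-3d":
            d1 = np.where(self.depth_t1.valid, self.depth_t1.depth, np.nan)
            d1_at = map_coordinates(
                d1, np.stack([target[..., 1].ravel(), target[..., 0].ravel()]),
                order=1, cval=np.nan,
            ).reshape(h, w)
            sel &= np.isfinite(d1_at) & (d1_at > 0)
            self._d1_at = d1_at
        self._sel = sel
        idx = np.flatnonzero(sel)
        self._rows, self._cols = np.unravel_index(idx, (h, w))
        pu, pv = u[sel], v[sel]
        Z = self.depth_t.depth[sel]
        self._X = np.stack(
            [Z * (pu - intr.cx) / intr.fx, Z * (pv - intr.cy) / intr.fy, Z], axis=-1
        )
        self._obs = target[sel]
        if self.options.residual == "alignment-3d":
            Z1 = self._d1_at[sel]
            self._Y = np.stack(
                [
                    Z1 * (self._obs[:, 0] - intr.cx) / intr.fx,
                    Z1 * (self._obs[:, 1] - intr.cy) / intr.fy,
                    Z1,
                ],
                axis=-1,
            )
        self._w = self.weights.values[sel]

    @property
    def n_pixels(self) -> int:
        return self._X.shape[0]

    # -- residuals and jacobians --------------------------------------------

    def residual_vectors(self, pose: RelativePose) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel residual vectors (n, k) and a front-of-camera mask (n,).

        ``k`` is 2 (px) for the reprojection residual, 3 (mm) for the
        alignment residual; both carry the sqrt(1/HW) normalization.
        Pixels transformed behind the camera are flagged, not raised.
        """
        intr = self.intrinsics
        Xp = self._X @ pose.rotation.T + pose.translation
        front = Xp[:, 2] > 0
        if self.options.residual == "reprojection-2d":
            r = np.zeros((self.n_pixels, 2))
            Zp = np.where(front, Xp[:, 2], 1.0)
            proj = np.stack(
                [
                    intr.fx * Xp[:, 0] / Zp + intr.cx,
                    intr.fy * Xp[:, 1] / Zp + intr.cy,
                ],
                axis=-1,
            )
            r[front] = (proj - self._obs)[front]
        else:
            r = Xp - self._Y
        return self._norm * r, front

    def residuals(self, pose: RelativePose) -> np.ndarray:
        """Scalar per-pixel residual norms (n,), normalized."""
        r, front = self.residual_vectors(pose)
        out = np.linalg.norm(r, axis=-1)
        out[~front] = np.nan
        return out

    def objective(self, pose: RelativePose) -> float:
        r, front = self.residual_vectors(pose)
        w = np.where(front, self._w, 0.0)
        sq = np.sum(r**2, axis=-1)
        if self.options.huber_delta is not None:
            d = self.options.huber_delta
            rho = np.where(sq <= d * d, sq, 2 * d * np.sqrt(sq) - d * d)
            return float(np.sum(w * rho))
        return float(np.sum(w * sq))

    def _jacobian_analytic(self, pose: RelativePose) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Residual vectors, effective weights, jacobians (n, k, 6).

        Derivatives are taken w.r.t. a left-multiplicative twist update
        ``T <- exp(xi) T``: for the transformed point ``X' = T X``,
        ``dX'/dxi = [I | -hat(X')]``.
        """
        intr = self.intrinsics
        Xp = self._X @ pose.rotation.T + pose.translation
        front = Xp[:, 2] > 0
        n = self.n_pixels
        Jpose = np.concatenate([np.tile(np.eye(3), (n, 1, 1)), -_hat_batch(Xp)], axis=2)
        r, _ = self.residual_vectors(pose)
        if self.options.residual == "reprojection-2d":
            Z = np.where(front, Xp[:, 2], 1.0)
            Jproj = np.zeros((n, 2, 3))
            Jproj[:, 0, 0] = intr.fx / Z
            Jproj[:, 0, 2] = -intr.fx * Xp[:, 0] / Z**2
            Jproj[:, 1, 1] = intr.fy / Z
            Jproj[:, 1, 2] = -intr.fy * Xp[:, 1] / Z**2
            J = self._norm * np.einsum("nij,njk->nik", Jproj, Jpose)
        else:
            J = self._norm * Jpose
        w = np.where(front, self._w, 0.0)
        if self.options.huber_delta is not None:
            norm = np.linalg.norm(r, axis=-1)
            d = self.options.huber_delta
            w = w * np.where(norm <= d, 1.0, d / np.maximum(norm, 1e-300))
        return r, w, J

    def _jacobian_numeric(self, pose: RelativePose, eps: float = 1e-6):
        r0, front = self.residual_vectors(pose)
        n, k = r0.shape
        J = np.zeros((n, k, 6))
        for j in range(6):
            xi = np.zeros(6)
            xi[j] = eps
            rp, _ = self.residual_vectors(compose(se3_exp(xi), pose))
            rm, _ = self.residual_vectors(compose(se3_exp(-xi), pose))
            J[:, :, j] = (rp - rm) / (2 * eps)
        w = np.where(front, self._w, 0.0)
        return r0, w, J

    def jacobian(self, pose: RelativePose):
        if self.options.jacobian == "numeric":
            return self._jacobian_numeric(pose)
        return self._jacobian_analytic(pose)

    def gauss_newton_step(self, pose: RelativePose, damping: float = 0.0) -> np.ndarray:
        """The (damped) normal-equations twist update at ``pose``."""
        r, w, J = self.jacobian(pose)
        H = np.einsum("n,nki,nkj->ij", w, J, J)
        g = np.einsum("n,nki,nk->i", w, J, r)
        return -np.linalg.solve(H + damping * np.eye(6), g)

    # -- fitting -------------------------------------------------------------

    def fit(self, start_pose: RelativePose | None = None) -> "RelativePoseResults":
        """Minimize the weighted objective by Levenberg-Marquardt.

        Starts from the identity unless ``start_pose`` is given.  Raises
        :class:`DegenerateProblemError` when fewer than 6 usable pixels or
        (numerically) zero total weight remain: the scene offers no rigid
        anchor.
        """
        opts = self.options
        if self.n_pixels < 6 or np.sum(self._w) < 1e-12:
            raise DegenerateProblemError(
                "fewer than 6 weighted pixels available: no rigid anchor"
            )
        pose = start_pose or identity_pose()
        lam = opts.lm_lambda0
        obj = self.objective(pose)
        converged = False
        iterations = 0
        for _ in range(opts.max_iterations):
            iterations += 1
            r, w, J = self.jacobian(pose)
            H = np.einsum("n,nki,nkj->ij", w, J, J)
            g = np.einsum("n,nki,nk->i", w, J, r)
            accepted = False
            for _trial in range(12):
                try:
                    delta = -np.linalg.solve(H + lam * np.eye(6), g)
                except np.linalg.LinAlgError:
                    lam *= opts.lm_factor
                    continue
                candidate = compose(se3_exp(delta), pose)
                cand_obj = self.objective(candidate)
                if cand_obj <= obj:
                    pose, obj = candidate, cand_obj
                    lam = max(lam / opts.lm_factor, 1e-12)
                    accepted = True
                    break
                lam *= opts.lm_factor
            if not accepted:
                converged = True  # no descent direction left at max damping
                break
            if np.linalg.norm(delta) < opts.tol:
                converged = True
                break
        res_grid = np.full(self.depth_t.shape, np.nan)
        res = self.residuals(pose)
        res_grid[self._rows, self._cols] = res
        return RelativePoseResults(
            model=self,
            pose=pose,
            residual_grid=res_grid,
            iterations=iterations,
            converged=converged,
            objective_value=obj,
        )


@dataclass
class RelativePoseResults:
    """Fitted relative pose with diagnostics.

    ``residual_grid`` holds the final normalized per-pixel residual norms
    (NaN where the pixel was unusable); the objective equals
    ``sum(W * residual^2)`` over that grid.
    """

    model: RelativePoseModel
    pose: RelativePose
    residual_grid: np.ndarray
    iterations: int
    converged: bool
    objective_value: float
    refinement_warning: bool = False

    @property
    def n_pixels(self) -> int:
        return self.model.n_pixels

    def recompute_objective(self) -> float:
        """Re-derive the objective from the stored residual grid and weights."""
        r = self.residual_grid
        ok = np.isfinite(r)
        return float(np.sum(self.model.weights.values[ok] * r[ok] ** 2))

    def unnormalized_residuals(self) -> np.ndarray:
        """Per-pixel residual norms without the sqrt(1/HW) factor."""
        return self.residual_grid / self.model._norm

    def refine(
        self, mode: str = "weighted", inlier_factor: float = 3.0
    ) -> "RelativePoseResults":
        """Re-optimize on inlier pixels, starting from the current pose.

        Inliers are usable pixels whose unnormalized residual is at most
        ``inlier_factor`` times the median.  ``mode='weighted'`` keeps the
        model's weight map on the inliers; ``mode='vanilla'`` uses constant
        weights there.  With no inliers the current results are returned
        unchanged with ``refinement_warning`` set.
        """
        if mode not in ("weighted", "vanilla"):
            raise ValueError("mode must be 'weighted' or 'vanilla'")
        res = self.unnormalized_residuals()
        ok = np.isfinite(res)
        if not ok.any():
            return replace(self, refinement_warning=True)
        threshold = inlier_factor * np.median(res[ok])
        inlier = ok & (res <= threshold)
        if not inlier.any():
            warnings.warn("refinement found no inliers; keeping the first pass")
            return replace(self, refinement_warning=True)
        base = self.model.weights.values if mode == "weighted" else np.ones_like(res)
        new_w = WeightMap(np.where(inlier, base, 0.0))
        refined_model = RelativePoseModel(
            self.model.flow_fwd,
            self.model.depth_t,
            self.model.intrinsics,
            weights=new_w,
            depth_t1=self.model.depth_t1,
            options=self.model.options,
        )
        return refined_model.fit(start_pose=self.pose)

    def summary(self) -> str:
        t = self.pose.translation
        rot_angle = np.rad2deg(
            np.arccos(np.clip((np.trace(self.pose.rotation) - 1) / 2, -1, 1))
        )
        lines = [
            "Weighted relative-pose estimation",
            "=" * 46,
            f"residual kind        {self.model.options.residual}",
            f"pixels used          {self.n_pixels}",
            f"total weight         {np.sum(self.model._w):.1f}",
            f"iterations           {self.iterations}"
            + ("  (converged)" if self.converged else "  (iteration cap)"),
            f"objective            {self.objective_value:.6e}",
            f"translation [mm]     ({t[0]:+.4f}, {t[1]:+.4f}, {t[2]:+.4f})",
            f"|translation| [mm]   {np.linalg.norm(t):.4f}",
            f"rotation angle [deg] {rot_angle:.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)


# -- functional wrappers ----------------------------------------------------


def estimate_pose(
    flow_fwd: FlowField,
    depth_t: DepthMap,
    intrinsics: CameraIntrinsics,
    weights: WeightMap | None = None,
    depth_t1: DepthMap | None = None,
    options: ResidualOptions | None = None,
    init: RelativePose | None = None,
) -> RelativePoseResults:
    """Build a :class:`RelativePoseModel` and fit it."""
    model = RelativePoseModel(
        flow_fwd, depth_t, intrinsics, weights=weights, depth_t1=depth_t1, options=options
    )
    return model.fit(start_pose=init)


def refine_pose(
    est: RelativePoseResults, mode: str = "weighted", inlier_factor: float = 3.0
) -> RelativePoseResults:
    """Inlier refinement of a fitted pose (see :meth:`RelativePoseResults.refine`)."""
    return est.refine(mode=mode, inlier_factor=inlier_factor)


def chain_poses(relatives: list[RelativePose]) -> Trajectory:
    """Chain relative poses ``P_{k+1,k}`` into camera-to-world absolutes.

    Pose 0 is the identity reference; pose k is
    ``pose_{k-1} o inverse(P_{k,k-1})``.
    """
    if len(relatives) < 1:
        raise ValueError("need at least one relative pose")
    poses = [identity_pose()]
    for rel in relatives:
        poses.append(compose(poses[-1], inverse(rel)))
    return Trajectory(poses)


def pose_l1_loss(est: RelativePose, gt: RelativePose) -> float:
    """Element-wise L1 distance between the [R | t] matrices."""
    return float(np.abs(est.matrix34() - gt.matrix34()).sum())
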