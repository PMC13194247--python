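"""Trajectory and motion-map evaluation.

RPE splits the per-frame-pair error between estimated and ground-truth
relative motions into translation (mm) and rotation (deg) components and
reports means at a frame delta of 1; ATE is the RMSE of camera positions
after a closed-form rigid (no-scale Umeyama) alignment.  These follow the
standard TUM-benchmark definitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import RelativePose, Trajectory, compose, inverse

__all__ = ["rpe", "ate", "umeyama_alignment", "EvalReport", "evaluate_run"]


def _rotation_angle_deg(R: np.ndarray) -> float:
    return float(np.rad2deg(np.arccos(np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0))))


def rpe(
    traj_est: Trajectory, traj_gt: Trajectory, delta: int = 1
) -> tuple[float, float]:
    """Mean relative pose error: (translation mm, rotation deg).

    For each index i the error motion is
    ``E_i = (gt_i^{-1} gt_{i+delta})^{-1} (est_i^{-1} est_{i+delta})``;
    the translation error is ``||trans(E_i)||`` and the rotation error the
    rotation angle of ``E_i``.
    """
    if len(traj_est) != len(traj_gt):
        raise ValueError("trajectories must have equal length")
    n = len(traj_gt)
    if n < delta + 1:
        raise ValueError("trajectory too short for the requested delta")
    t_errs, r_errs = [], []
    for i in range(n - delta):
        rel_gt = traj_gt.relative(i, i + delta)
        rel_est = traj_est.relative(i, i + delta)
        E = compose(inverse(rel_gt), rel_est)
        t_errs.append(np.linalg.norm(E.translation))
        r_errs.append(_rotation_angle_deg(E.rotation))
    return float(np.mean(t_errs)), float(np.mean(r_errs))


def umeyama_alignment(src: np.ndarray, dst: np.ndarray) -> RelativePose:
    """Closed-form rigid (no scale) least-squares alignment ``dst ~ R src + t``."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    cov = (dst - mu_d).T @ (src - mu_s) / src.shape[0]
    U, _, Vt = np.linalg.svd(cov)
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    return RelativePose(R, mu_d - R @ mu_s)


def ate(traj_est: Trajectory, traj_gt: Trajectory, align: bool = True) -> float:
    """Absolute trajectory error: position RMSE (mm) after rigid alignment.

    Degenerate inputs (all estimated positions identical) skip the
    alignment and compare directly.
    """
    if len(traj_est) != len(traj_gt):
        raise ValueError("trajectories must have equal length")
    if len(traj_gt) < 2:
        raise ValueError("need at least 2 poses")
    p_est = traj_est.positions()
    p_gt = traj_gt.positions()
    if align:
        spread = np.ptp(p_est, axis=0).max()
        if spread > 1e-12:
            T = umeyama_alignment(p_est, p_gt)
            p_est = T.apply(p_est)
        else:
            p_est = p_est + (p_gt.mean(axis=0) - p_est.mean(axis=0))
    return float(np.sqrt(np.mean(np.sum((p_est - p_gt) ** 2, axis=1))))


@dataclass
class EvalReport:
    """Per-sequence metrics with per-scenario aggregation.

    ``sequences`` maps a sequence name to a dict with keys
    ``scenario, rpe_trans_mm, rpe_rot_deg, ate_mm`` and, where motion maps
    and non-static ground truth exist, ``iou_pct``.
    """

    sequences: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def add(self, name: str, scenario: str, metrics: dict) -> None:
        for key in ("rpe_trans_mm", "rpe_rot_deg", "ate_mm"):
            if key in metrics and metrics[key] < 0:
                raise ValueError(f"{key} must be non-negative")
        if "iou_pct" in metrics and not (0 <= metrics["iou_pct"] <= 100):
            raise ValueError("iou_pct must lie in [0, 100]")
        self.sequences[name] = {"scenario": scenario, **metrics}

    def by_scenario(self) -> dict:
        """Mean of every numeric metric within each scenario."""
        groups: dict[str, list[dict]] = {}
        for entry in self.sequences.values():
            groups.setdefault(entry["scenario"], []).append(entry)
        out = {}
        for scen, entries in sorted(groups.items()):
            keys = sorted(
                {k for e in entries for k in e if k != "scenario" and e[k] is not None}
            )
            out[scen] = {
                k: float(np.mean([e[k] for e in entries if e.get(k) is not None]))
                for k in keys
            }
            out[scen]["n_sequences"] = len(entries)
        return out

    def to_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "sequences": self.sequences,
            "scenarios": self.by_scenario(),
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text

    def table(self) -> str:
        """A human-readable per-scenario table."""
        rows = self.by_scenario()
        cols = ["rpe_trans_mm", "rpe_rot_deg", "ate_mm", "iou_pct"]
        header = f"{'scenario':<18}" + "".join(f"{c:>14}" for c in cols) + f"{'n':>5}"
        lines = [header, "-" * len(header)]
        for scen, vals in rows.items():
            line = f"{scen:<18}"
            for c in cols:
                line += f"{vals[c]:>14.4f}" if c in vals else f"{'-':>14}"
            line += f"{vals['n_sequences']:>5d}"
            lines.append(line)
        return "\n".join(lines)


def evaluate_run(
    sample,
    traj_est: Trajectory,
    motion_maps: list | None = None,
    iou_threshold: float = 0.5,
) -> dict:
    """Metrics for one sequence: RPE, ATE and (if applicable) mean IoU.

    ``sample`` is a generated or loaded :class:`~dynvo.synth.StereoSequenceSample`
    carrying the ground-truth trajectory and motion masks.  IoU is omitted
    (set to None) for static-content scenarios, where there is no motion to
    detect.
    """
    from .motion import motion_iou

    t_err, r_err = rpe(traj_est, sample.trajectory)
    metrics = {
        "rpe_trans_mm": t_err,
        "rpe_rot_deg": r_err,
        "ate_mm": ate(traj_est, sample.trajectory),
    }
    is_static = sample.scenario is not None and sample.scenario.content == "static"
    if motion_maps is not None and not is_static:
        ious = [
            motion_iou(m, sample.motion_mask[t], threshold=iou_threshold)
            for t, m in enumerate(motion_maps)
            if m is not None
        ]
        if ious:
            metrics["iou_pct"] = float(np.mean(ious))
    return metrics
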