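"""Shared fixtures: small camera rigs and the generated study suites.

The heavier suites (20 static sequences, 20 dynamic-tissue sequences with
all estimator variants) are computed once per session and shared across the
property and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from dynvo.geometry import CameraIntrinsics
from dynvo.metrics import rpe
from dynvo.motion import (
    MotionProbabilityMap,
    flow_consistency_motion,
    motion_iou,
    weight_from_motion,
)
from dynvo.pose import RelativePoseModel, ResidualOptions, chain_poses
from dynvo.synth import generate_sequence, with_depth_noise, with_flow_noise

N_SUITE = 20
N_FRAMES = 6
FLOW_NOISE_PX = 0.2
DEPTH_NOISE_FRAC = 0.02


@pytest.fixture
def intr_small() -> CameraIntrinsics:
    """A tiny rig for cheap unit tests."""
    return CameraIntrinsics(
        fx=80.0, fy=80.0, cx=31.5, cy=23.5, width=64, height=48, baseline=4.2
    )


@pytest.fixture
def intr_square() -> CameraIntrinsics:
    """The worked-example rig: fx=fy=100, principal point (50, 50), 100x100."""
    return CameraIntrinsics(
        fx=100.0, fy=100.0, cx=50.0, cy=50.0, width=100, height=100, baseline=5.0
    )


def _fit(flow, depth, intr, weights=None, depth_t1=None, options=None, init=None):
    model = RelativePoseModel(
        flow, depth, intr, weights=weights, depth_t1=depth_t1, options=options
    )
    return model.fit(start_pose=init)


@pytest.fixture(scope="session")
def scenario_samples():
    """One short sequence per scenario (exact ground truth, no noise)."""
    from dynvo.synth import SCENARIOS

    return {
        scen.name: generate_sequence(scen, n_frames=4, seed=100 + i)
        for i, scen in enumerate(SCENARIOS)
    }


@pytest.fixture(scope="session")
def static_suite():
    """20 moving-camera rigid-scene sequences with exact and noisy fits.

    Per frame pair: the constant-weight estimate on exact inputs and on
    inputs with 0.2 px flow noise, plus the generating relative pose.
    """
    records = []
    for i in range(N_SUITE):
        sample = generate_sequence("S0-static", n_frames=N_FRAMES, seed=1000 + i)
        rng = np.random.default_rng(np.random.SeedSequence([2024, i]))
        noisy = with_flow_noise(sample, FLOW_NOISE_PX, rng)
        pairs = []
        for t in range(sample.n_frames - 1):
            gt = sample.relative_pose(t)
            exact = _fit(sample.flow_fwd[t], sample.depth[t], sample.intrinsics)
            noised = _fit(noisy.flow_fwd[t], noisy.depth[t], sample.intrinsics)
            pairs.append({"gt": gt, "exact": exact, "noisy": noised})
        records.append({"sample": sample, "pairs": pairs})
    return records


@pytest.fixture(scope="session")
def dynamic_suite():
    """20 moving-camera deforming-tissue sequences with the estimator matrix.

    The moving layer covers roughly 15-30% of the frame; temporal flows
    carry 0.2 px Gaussian noise.  Per sequence: sequence-level RPE of the
    naive, ground-truth-mask-weighted, flow-consistency-weighted and
    refined (weighted inliers) estimators; per-pair flow-consistency IoU;
    and, under 2% multiplicative depth noise, the 2D-reprojection vs
    3D-alignment weighted estimates.
    """
    opts3d = ResidualOptions(residual="alignment-3d")
    records = []
    for i in range(N_SUITE):
        sample = generate_sequence("S0-tissue", n_frames=N_FRAMES, seed=3000 + i)
        rng = np.random.default_rng(np.random.SeedSequence([2025, i]))
        noisy = with_flow_noise(sample, FLOW_NOISE_PX, rng)
        depth_noisy = with_depth_noise(noisy, DEPTH_NOISE_FRAC, rng)
        intr = sample.intrinsics
        rel = {"naive": [], "gtw": [], "fcw": [], "rfw": [], "d2": [], "d3": []}
        ious = []
        for t in range(sample.n_frames - 1):
            flow, depth = noisy.flow_fwd[t], noisy.depth[t]
            naive = _fit(flow, depth, intr)
            gt_w = weight_from_motion(
                MotionProbabilityMap(sample.motion_mask[t].astype(float))
            )
            gtw = _fit(flow, depth, intr, weights=gt_w)
            M = flow_consistency_motion(flow, depth, naive.pose, intr, sigma=1.0)
            ious.append(motion_iou(M, sample.motion_mask[t]))
            fcw = _fit(flow, depth, intr, weights=weight_from_motion(M))
            rfw = fcw.refine(mode="weighted")
            d2 = _fit(
                depth_noisy.flow_fwd[t], depth_noisy.depth[t], intr, weights=gt_w
            )
            d3 = _fit(
                depth_noisy.flow_fwd[t],
                depth_noisy.depth[t],
                intr,
                weights=gt_w,
                depth_t1=depth_noisy.depth[t + 1],
                options=opts3d,
            )
            for key, est in [
                ("naive", naive), ("gtw", gtw), ("fcw", fcw),
                ("rfw", rfw), ("d2", d2), ("d3", d3),
            ]:
                rel[key].append(est.pose)
        seq_rpe = {
            key: rpe(chain_poses(poses), sample.trajectory)
            for key, poses in rel.items()
        }
        coverage = float(np.mean([m.mean() for m in sample.moving_support]))
        records.append(
            {
                "sample": sample,
                "rpe": seq_rpe,
                "iou": float(np.mean(ious)),
                "coverage": coverage,
            }
        )
    return records
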