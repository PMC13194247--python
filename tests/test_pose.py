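"""Weighted pose optimization: residuals, LM fitting, refinement, chaining."""

import numpy as np
import pytest

from dynvo.geometry import (
    DepthMap,
    FlowField,
    identity_pose,
    se3_exp,
    translation_pose,
)
from dynvo.motion import WeightMap, constant_weight
from dynvo.pose import (
    DegenerateProblemError,
    RelativePoseModel,
    ResidualOptions,
    chain_poses,
    estimate_pose,
    pose_l1_loss,
    refine_pose,
)


def _flat_scene(intr, depth_mm=100.0):
    h, w = intr.shape
    return FlowField(np.zeros((h, w, 2))), DepthMap(np.full((h, w), depth_mm))


class TestReprojectionResidual:
    def test_identity_zero_flow_zero_residual(self, intr_square):
        flow, depth = _flat_scene(intr_square)
        model = RelativePoseModel(flow, depth, intr_square)
        assert np.nanmax(model.residuals(identity_pose())) == 0.0

    def test_hand_computed_translation_residual(self, intr_square):
        # depth 100 mm everywhere, pose = +1 mm in X, observed flow 0:
        # every projected point shifts by fx/100 = 1 px, so the normalized
        # residual is sqrt(1/10^4) * 1 = 0.01 at every pixel
        flow, depth = _flat_scene(intr_square, 100.0)
        model = RelativePoseModel(flow, depth, intr_square)
        res = model.residuals(translation_pose(1.0, 0, 0))
        assert np.allclose(res, 0.01, atol=1e-12)

    def test_zero_at_generating_pose_on_synthetic_sample(self, scenario_samples):
        sample = scenario_samples["S0-static"]
        model = RelativePoseModel(sample.flow_fwd[0], sample.depth[0], sample.intrinsics)
        assert np.nanmax(model.residuals(sample.relative_pose(0))) < 1e-9


class TestAlignmentResidual3D:
    def test_identity_zero(self, intr_square):
        flow, depth = _flat_scene(intr_square)
        model = RelativePoseModel(
            flow, depth, intr_square, depth_t1=depth,
            options=ResidualOptions(residual="alignment-3d"),
        )
        assert np.nanmax(model.residuals(identity_pose())) == 0.0

    def test_requires_second_depth(self, intr_square):
        flow, depth = _flat_scene(intr_square)
        with pytest.raises(ValueError):
            RelativePoseModel(
                flow, depth, intr_square, options=ResidualOptions(residual="alignment-3d")
            )

    def test_zero_on_exact_synthetic_rigid_pixels(self, scenario_samples):
        sample = scenario_samples["S0-static"]
        model = RelativePoseModel(
            sample.flow_fwd[0], sample.depth[0], sample.intrinsics,
            depth_t1=sample.depth[1],
            options=ResidualOptions(residual="alignment-3d"),
        )
        # bilinear depth interpolation on the curved surface leaves a tiny
        # sub-micrometre residual; the generating pose is a near-exact zero
        assert np.nanmax(model.residuals(sample.relative_pose(0))) < 1e-4

    def test_depth_noise_inflates_residual(self, intr_square):
        rng = np.random.default_rng(0)
        flow, depth = _flat_scene(intr_square)
        noisy_d1 = DepthMap(depth.depth * (1 + 0.02 * rng.normal(size=depth.shape)))
        model = RelativePoseModel(
            flow, depth, intr_square, depth_t1=noisy_d1,
            options=ResidualOptions(residual="alignment-3d"),
        )
        res = model.residuals(identity_pose())
        assert np.nanmean(res) > 0
        # scale ~ sigma_D * sqrt(1/HW) = 2 mm * 0.01
        assert 0.2 * 0.02 < np.nanmean(res) < 5 * 0.02


class TestEstimatePose:
    def test_zero_weights_degenerate(self, intr_square):
        flow, depth = _flat_scene(intr_square)
        with pytest.raises(DegenerateProblemError):
            estimate_pose(flow, depth, intr_square, weights=WeightMap(np.zeros(depth.shape)))

    def test_too_few_pixels_degenerate(self, intr_square):
        flow, depth = _flat_scene(intr_square)
        depth.valid[:] = False
        depth.valid[0, :4] = True
        with pytest.raises(DegenerateProblemError):
            estimate_pose(flow, depth, intr_square)

    def test_weight_shape_mismatch_rejected(self, intr_square):
        flow, depth = _flat_scene(intr_square)
        with pytest.raises(ValueError):
            RelativePoseModel(flow, depth, intr_square, weights=constant_weight((10, 10)))

    def test_recovers_generating_pose_exactly(self, scenario_samples):
        sample = scenario_samples["S0-static"]
        res = estimate_pose(sample.flow_fwd[0], sample.depth[0], sample.intrinsics)
        gt = sample.relative_pose(0)
        assert np.linalg.norm(res.pose.translation - gt.translation) < 1e-3
        ang = np.rad2deg(
            np.arccos(np.clip((np.trace(res.pose.rotation.T @ gt.rotation) - 1) / 2, -1, 1))
        )
        assert ang < 1e-3

    def test_iteration_cap_respected(self, scenario_samples):
        sample = scenario_samples["S0-static"]
        res = estimate_pose(
            sample.flow_fwd[0], sample.depth[0], sample.intrinsics,
            options=ResidualOptions(max_iterations=1),
        )
        assert res.iterations == 1

    def test_objective_recomputable_from_stored_channels(self, scenario_samples):
        sample = scenario_samples["S0-tissue"]
        res = estimate_pose(sample.flow_fwd[0], sample.depth[0], sample.intrinsics)
        assert np.isclose(res.objective_value, res.recompute_objective(), atol=1e-9)

    def test_objective_not_above_identity_start(self, scenario_samples):
        sample = scenario_samples["S0-tissue"]
        model = RelativePoseModel(sample.flow_fwd[0], sample.depth[0], sample.intrinsics)
        assert model.fit().objective_value <= model.objective(identity_pose()) + 1e-15

    def test_stride_subsampling_still_accurate(self, scenario_samples):
        sample = scenario_samples["S0-static"]
        res = estimate_pose(
            sample.flow_fwd[0], sample.depth[0], sample.intrinsics,
            options=ResidualOptions(stride=4),
        )
        gt = sample.relative_pose(0)
        assert np.linalg.norm(res.pose.translation - gt.translation) < 1e-3

    def test_summary_reports_key_quantities(self, scenario_samples):
        sample = scenario_samples["S0-static"]
        res = estimate_pose(sample.flow_fwd[0], sample.depth[0], sample.intrinsics)
        text = res.summary()
        assert "reprojection-2d" in text
        assert "iterations" in text


class TestOptimizerOracles:
    def test_gauss_newton_step_matches_weighted_lstsq(self, intr_square):
        # linear instance: 3D residual with identity rotation is linear in
        # the translation; one undamped GN step from identity must equal the
        # closed-form weighted linear least-squares solution on the same
        # 10-pixel problem, computed independently via lstsq
        rng = np.random.default_rng(8)
        h, w = intr_square.shape
        depth = np.full((h, w), np.nan)
        rows = rng.choice(h * w, size=10, replace=False)
        depth.flat[rows] = rng.uniform(50, 150, size=10)
        flow = FlowField(np.zeros((h, w, 2)))
        model = RelativePoseModel(
            flow, DepthMap(depth), intr_square, depth_t1=DepthMap(np.full((h, w), 100.0)),
            options=ResidualOptions(residual="alignment-3d", jacobian="numeric"),
        )
        weights = rng.uniform(0.2, 1.0, size=model.n_pixels)
        model._w = weights
        step = model.gauss_newton_step(identity_pose(), damping=0.0)
        r, wts, J = model.jacobian(identity_pose())
        sw = np.sqrt(wts)
        A = (J * sw[:, None, None]).reshape(-1, 6)
        b = -(r * sw[:, None]).reshape(-1)
        expected, *_ = np.linalg.lstsq(A, b, rcond=None)
        assert np.allclose(step, expected, atol=1e-9)

    @pytest.mark.parametrize("residual", ["reprojection-2d", "alignment-3d"])
    def test_finite_difference_jacobian_matches_analytic(self, residual, scenario_samples):
        sample = scenario_samples["S0-tissue"]
        kwargs = dict(depth_t1=sample.depth[1])
        pose = se3_exp(np.array([0.3, -0.2, 0.1, 0.002, -0.001, 0.003]))
        m_an = RelativePoseModel(
            sample.flow_fwd[0], sample.depth[0], sample.intrinsics,
            options=ResidualOptions(residual=residual, stride=7), **kwargs,
        )
        m_fd = RelativePoseModel(
            sample.flow_fwd[0], sample.depth[0], sample.intrinsics,
            options=ResidualOptions(residual=residual, stride=7, jacobian="numeric"),
            **kwargs,
        )
        _, _, J_an = m_an.jacobian(pose)
        _, _, J_fd = m_fd.jacobian(pose)
        scale = np.abs(J_an).max()
        assert np.allclose(J_an, J_fd, atol=1e-5 * scale)


class TestRefinement:
    def test_noise_free_scene_is_fixed_point(self, scenario_samples):
        sample = scenario_samples["S0-static"]
        first = estimate_pose(sample.flow_fwd[0], sample.depth[0], sample.intrinsics)
        refined = refine_pose(first, mode="weighted")
        assert np.allclose(refined.pose.matrix(), first.pose.matrix(), atol=1e-6)
        assert not refined.refinement_warning

    def test_both_modes_computed(self, scenario_samples):
        sample = scenario_samples["S0-tissue"]
        first = estimate_pose(sample.flow_fwd[0], sample.depth[0], sample.intrinsics)
        for mode in ("weighted", "vanilla"):
            refined = first.refine(mode=mode)
            assert refined.iterations >= 1
        with pytest.raises(ValueError):
            first.refine(mode="bogus")


class TestChainingAndLoss:
    def test_identities_chain_to_identities(self):
        traj = chain_poses([identity_pose()] * 3)
        for p in traj.poses:
            assert np.allclose(p.matrix(), np.eye(4))

    def test_two_steps_accumulate(self):
        # each relative pose maps frame-t coords into frame-t+1: a camera
        # advancing +1 mm in X gives P with translation (-1, 0, 0)
        rel = translation_pose(-1.0, 0, 0)
        traj = chain_poses([rel, rel])
        assert np.isclose(np.linalg.norm(traj.poses[2].translation), 2.0)

    def test_requires_at_least_one(self):
        with pytest.raises(ValueError):
            chain_poses([])

    def test_l1_loss_examples(self):
        gt = translation_pose(0, 0, 0)
        assert pose_l1_loss(gt, gt) == 0.0
        assert np.isclose(pose_l1_loss(translation_pose(1, 0, 0), gt), 1.0)

    def test_l1_loss_matches_brute_force(self):
        rng = np.random.default_rng(12)
        a = se3_exp(rng.normal(scale=0.3, size=6))
        b = se3_exp(rng.normal(scale=0.3, size=6))
        expected = sum(
            abs(a.matrix34().flat[i] - b.matrix34().flat[i]) for i in range(12)
        )
        assert np.isclose(pose_l1_loss(a, b), expected, atol=1e-12)
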