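"""Synthetic scene generator: TPS warps, motion models, composition, dataset."""

import numpy as np
import pytest
import yaml

from dynvo.geometry import backproject, depth_from_stereo_flow, project
from dynvo.synth import (
    SCENARIOS,
    BackgroundSurface,
    DegenerateControlsError,
    HomographyBounds,
    MotionScale,
    Scenario,
    compose_sequence,
    generate_dataset,
    generate_sequence,
    make_tissue_layer,
    make_tool_layer,
    read_sequence,
    render_background,
    sample_trajectory,
    simulate_tissue_deformation,
    simulate_tool_motion,
    tps_fit,
)


class TestThinPlateSpline:
    def grid(self, n=4, spacing=10.0):
        g = np.stack(np.meshgrid(np.arange(n), np.arange(n)), -1).reshape(-1, 2)
        return g * spacing

    def test_identity_has_zero_kernel_weights(self):
        src = self.grid()
        warp = tps_fit(src, src)
        assert np.allclose(warp.kernel_weights, 0, atol=1e-9)
        q = np.array([[3.3, 7.7], [11.0, 2.5]])
        assert np.allclose(warp(q), q, atol=1e-9)

    def test_affine_relation_reproduced_exactly(self):
        rng = np.random.default_rng(4)
        src = self.grid()
        A = np.eye(2) + rng.normal(scale=0.2, size=(2, 2))
        b = rng.normal(scale=5, size=2)
        warp = tps_fit(src, src @ A.T + b)
        q = rng.uniform(-10, 40, size=(100, 2))
        assert np.allclose(warp(q), q @ A.T + b, atol=1e-6)
        assert np.allclose(warp.kernel_weights, 0, atol=1e-8)

    def test_interpolates_controls_and_decays(self):
        src = self.grid()
        dst = src.copy()
        dst[5] += [3.0, 0.0]  # control at (10, 10) displaced by (3, 0)
        warp = tps_fit(src, dst)
        assert np.allclose(warp(src), dst, atol=1e-9)
        # displacement decays with distance from the displaced control
        # (within the control hull, where the spline interpolates)
        probes = np.array([[10.0, 10.0], [15.0, 10.0], [22.0, 10.0], [31.0, 31.0]])
        disps = np.linalg.norm(warp(probes) - probes, axis=-1)
        assert disps[0] > 2.9
        assert disps[0] > disps[1] > disps[2] > disps[3]
        assert disps[3] < 0.1

    def test_matches_scipy_rbf_oracle(self):
        from scipy.interpolate import RBFInterpolator

        rng = np.random.default_rng(9)
        src = self.grid(5, 8.0)
        dst = src + rng.normal(scale=2.0, size=src.shape)
        mine = tps_fit(src, dst)
        oracle = RBFInterpolator(src, dst, kernel="thin_plate_spline", degree=1)
        q = rng.uniform(0, 32, size=(60, 2))
        assert np.allclose(mine(q), oracle(q), atol=1e-8)

    @pytest.mark.parametrize(
        "src",
        [
            np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]),  # collinear
            np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 2.0], [3.0, 1.0]]),  # duplicate
            np.array([[0.0, 0.0], [1.0, 1.0]]),  # too few
        ],
    )
    def test_degenerate_controls_rejected(self, src):
        with pytest.raises(DegenerateControlsError):
            tps_fit(src, src)


class TestTrajectorySampling:
    def test_still_camera_all_identity(self):
        traj = sample_trajectory(30, "S1", MotionScale(1, 0.5), seed=7)
        for pose in traj.poses:
            assert np.allclose(pose.matrix(), np.eye(4))

    def test_seed_determinism(self):
        a = sample_trajectory(30, "S0", MotionScale(1, 0.5), seed=7)
        b = sample_trajectory(30, "S0", MotionScale(1, 0.5), seed=7)
        for pa, pb in zip(a.poses, b.poses):
            assert np.allclose(pa.matrix(), pb.matrix())

    def test_per_frame_motion_bounds(self):
        scale = MotionScale(translation=1.0, rotation=0.5)
        traj = sample_trajectory(30, "S0", scale, seed=7)
        for t in range(len(traj) - 1):
            rel = traj.relative_pose(t)
            assert np.linalg.norm(rel.translation) <= scale.translation + 1e-9
            ang = np.rad2deg(np.arccos(np.clip((np.trace(rel.rotation) - 1) / 2, -1, 1)))
            assert ang <= scale.rotation + 1e-9
        # the camera actually moves
        assert max(np.linalg.norm(p.translation) for p in traj.poses) > 0.1


class TestMotionModels:
    def _tissue(self, intr):
        rng = np.random.default_rng(0)
        return make_tissue_layer(intr, rng, coverage=0.2)

    def _tool(self, intr):
        rng = np.random.default_rng(0)
        return make_tool_layer(intr, rng, coverage=0.1)

    def test_zero_max_disp_is_identity(self, intr_small):
        layer = self._tissue(intr_small)
        seq = simulate_tissue_deformation(layer, 10, max_disp=0.0, seed=3)
        assert np.allclose(seq.targets, seq.sources[None])

    def test_frame0_identity_and_displacement_bound(self, intr_small):
        layer = self._tissue(intr_small)
        seq = simulate_tissue_deformation(layer, 12, max_disp=8.0, seed=3)
        assert np.allclose(seq.targets[0], seq.sources)
        disp = np.linalg.norm(seq.targets - seq.sources[None], axis=-1)
        assert disp.max() <= 8.0 + 1e-9  # every control, every frame
        assert disp.max() > 1.0  # and it does deform

    def test_tissue_determinism(self, intr_small):
        layer = self._tissue(intr_small)
        a = simulate_tissue_deformation(layer, 8, seed=5)
        b = simulate_tissue_deformation(layer, 8, seed=5)
        assert np.array_equal(a.targets, b.targets)

    def test_tool_zero_bounds_identity(self, intr_small):
        layer = self._tool(intr_small)
        seq = simulate_tool_motion(layer, 8, HomographyBounds(0, 0, 0, 0), seed=1)
        for t in range(8):
            assert np.allclose(seq.matrices[t], np.eye(3), atol=1e-12)

    def test_tool_pure_translation_bounds(self, intr_small):
        layer = self._tool(intr_small)
        bounds = HomographyBounds(0, 5.0, 0, 0, reference_frames=8)
        seq = simulate_tool_motion(layer, 8, bounds, seed=2)
        for t in range(8):
            H = seq.matrices[t]
            assert np.allclose(H[:2, :2], np.eye(2), atol=1e-12)
            assert np.allclose(H[2, :2], 0, atol=1e-12)
            assert np.linalg.norm(H[:2, 2]) <= 5.0 * np.sqrt(2) + 1e-9
        # smoothstep reaches the target at the last frame
        assert np.linalg.norm(seq.matrices[-1][:2, 2]) > 0

    def test_tool_determinism_and_category_check(self, intr_small):
        layer = self._tool(intr_small)
        a = simulate_tool_motion(layer, 6, seed=4)
        b = simulate_tool_motion(layer, 6, seed=4)
        assert np.array_equal(a.matrices, b.matrices)
        with pytest.raises(ValueError):
            simulate_tool_motion(self._tissue(intr_small), 6, seed=0)


class TestBackground:
    def test_static_camera_zero_flow(self, intr_small):
        rng = np.random.default_rng(1)
        surface = BackgroundSurface.random(rng)
        traj = sample_trajectory(3, "S1", seed=0)
        bg = render_background(surface, traj, intr_small)
        for f in bg.flow_fwd:
            assert np.allclose(f.flow, 0, atol=1e-9)

    def test_fronto_parallel_plane_uniform_flow(self, intr_small):
        # flat plane at 100 mm, pure +X camera step of 1 mm, fx=80:
        # background flow is uniformly (-fx*tx/Z, 0) = (-0.8, 0)
        rng = np.random.default_rng(1)
        surface = BackgroundSurface(
            anchor=np.array([0.0, 0.0, 100.0]),
            normal=np.array([0.0, 0.0, -1.0]),
            texture=BackgroundSurface.random(rng).texture,
            bowl_depth=0.0,
        )
        from dynvo.geometry import Trajectory, translation_pose

        traj = Trajectory([translation_pose(0, 0, 0), translation_pose(1, 0, 0)])
        bg = render_background(surface, traj, intr_small)
        assert np.allclose(bg.flow_fwd[0].flow[..., 0], -0.8, atol=1e-9)
        assert np.allclose(bg.flow_fwd[0].flow[..., 1], 0.0, atol=1e-9)

    def test_stereo_flow_inverts_to_depth(self, intr_small):
        rng = np.random.default_rng(2)
        surface = BackgroundSurface.random(rng)
        traj = sample_trajectory(2, "S0", seed=3)
        bg = render_background(surface, traj, intr_small)
        for t in range(2):
            d = depth_from_stereo_flow(bg.flow_stereo[t], intr_small)
            assert d.valid.all()
            assert np.abs(d.depth - bg.depth[t].depth).max() < 1e-6
            # rectified rig: stereo flow is horizontal
            assert np.abs(bg.flow_stereo[t].flow[..., 1]).max() < 0.5


class TestScenario:
    def test_eight_scenarios(self):
        assert len(SCENARIOS) == 8
        assert len({s.name for s in SCENARIOS}) == 8

    def test_name_round_trip(self):
        for s in SCENARIOS:
            assert Scenario.from_name(s.name) == s

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            Scenario("S2", "tool")
        with pytest.raises(ValueError):
            Scenario("S0", "scalpel")


class TestComposition:
    def test_no_layers_equals_background(self, intr_small):
        rng = np.random.default_rng(3)
        surface = BackgroundSurface.random(rng)
        traj = sample_trajectory(3, "S0", seed=5)
        bg = render_background(surface, traj, intr_small)
        sample = compose_sequence(bg, [], traj, intr_small)
        for t in range(3):
            assert not sample.motion_mask[t].any()
            assert np.array_equal(sample.depth[t].depth, bg.depth[t].depth)
            assert np.array_equal(sample.left[t], bg.left[t])

    def test_still_tool_under_still_camera_has_empty_mask(self):
        sample = generate_sequence("S1-static", n_frames=3, seed=8)
        for m in sample.motion_mask:
            assert not m.any()

    def test_moving_tissue_mask_matches_support(self):
        sample = generate_sequence("S0-tissue", n_frames=4, seed=21)
        for t in range(sample.n_frames):
            sup = sample.moving_support[t].mean()
            mask = sample.motion_mask[t].mean()
            assert sup > 0.1  # the layer is actually in frame
            # nearly all support pixels exceed the 0.1 px motion threshold
            assert abs(mask - sup) <= 0.01 * max(sup, 1e-9) + 0.01

    def test_mask_flow_coherence(self):
        # the motion mask is exactly the 0.1 px threshold on the intrinsic
        # (non-rigid) displacement, and that displacement agrees with the
        # stored flow minus the camera-induced rigid flow at the layer depth
        sample = generate_sequence("S0-tissue", n_frames=4, seed=22)
        intr = sample.intrinsics
        t = 1
        sup = sample.layer_support[t]
        delta = sample.intrinsic_disp[t][sup]
        masked = sample.motion_mask[t][sup]
        assert np.array_equal(masked, delta > 0.1)
        layer_depth = sample.depth[t].depth[sup]
        u, v = intr.pixel_grid()
        px = np.stack([u, v], -1)[sup]
        pose = sample.relative_pose(t)
        anchoring = project(pose.apply(backproject(px, layer_depth, intr)), intr) - px
        flow_based = np.linalg.norm(sample.flow_fwd[t].flow[sup] - anchoring, axis=-1)
        # the stored flow tracks the intrinsic displacement up to the
        # backward-TPS inverse error (moving-tissue pixels are masked, so
        # this approximation never touches the rigid-pixel exactness)
        assert np.corrcoef(flow_based, delta)[0, 1] > 0.9
        assert np.median(np.abs(flow_based - delta)) < 1.0

    def test_layer_must_be_nearer_than_background(self, intr_small):
        rng = np.random.default_rng(6)
        surface = BackgroundSurface.random(rng)
        traj = sample_trajectory(2, "S1", seed=1)
        bg = render_background(surface, traj, intr_small)
        layer = make_tissue_layer(intr_small, rng, coverage=0.1)
        layer.depth = 1000.0  # behind the background
        with pytest.raises(ValueError):
            compose_sequence(bg, [layer], traj, intr_small)

    def test_forward_backward_consistency_on_background(self):
        from scipy.ndimage import map_coordinates

        sample = generate_sequence("S0-tissue", n_frames=3, seed=23)
        h, w = sample.depth[0].shape
        v, u = np.mgrid[0:h, 0:w].astype(float)
        t = 0
        tgt = np.stack([u, v], -1) + sample.flow_fwd[t].flow
        bwd = np.stack(
            [
                map_coordinates(
                    sample.flow_bwd[t].flow[..., c],
                    [tgt[..., 1].ravel(), tgt[..., 0].ravel()],
                    order=1, cval=np.nan,
                ).reshape(h, w)
                for c in range(2)
            ],
            -1,
        )
        err = np.linalg.norm(sample.flow_fwd[t].flow + bwd, axis=-1)
        inb = (tgt[..., 0] >= 1) & (tgt[..., 0] <= w - 2) & (tgt[..., 1] >= 1) & (tgt[..., 1] <= h - 2)
        # stay away from occlusion boundaries: exclude pixels on (or whose
        # flow target lands within 2 px of) any layer support
        from scipy.ndimage import binary_dilation

        sup_t = binary_dilation(sample.layer_support[t], iterations=2)
        sup_t1 = binary_dilation(sample.layer_support[t + 1], iterations=2)
        on_layer = sup_t | sup_t1
        tgt_on_layer = (
            map_coordinates(
                sup_t1.astype(float),
                [tgt[..., 1].ravel(), tgt[..., 0].ravel()],
                order=1, cval=1,
            ).reshape(h, w)
            > 0
        )
        rigid = inb & ~on_layer & ~tgt_on_layer
        assert rigid.mean() > 0.5
        assert np.nanmax(err[rigid]) < 1e-3

    def test_chaining_relatives_reproduces_trajectory(self):
        from dynvo.pose import chain_poses

        sample = generate_sequence("S0-static", n_frames=5, seed=24)
        rels = [sample.relative_pose(t) for t in range(4)]
        chained = chain_poses(rels)
        for a, b in zip(chained.poses, sample.trajectory.poses):
            assert np.allclose(a.matrix(), b.matrix(), atol=1e-9)


class TestDataset:
    def test_layout_counts_and_static_masks(self, tmp_path):
        out = tmp_path / "ds"
        manifest = generate_dataset(
            out, scenarios=["S0-static"], n_sequences=1, n_frames=4, seed=0
        )
        seq = out / manifest["sequences"][0]["name"]
        assert len(list((seq / "left").glob("*.png"))) == 4
        assert len(list((seq / "right").glob("*.png"))) == 4
        assert len(list((seq / "flow_fwd").glob("*.flo"))) == 3
        assert len(list((seq / "flow_bwd").glob("*.flo"))) == 3
        assert (seq / "traj_gt.tum").exists()
        sample = read_sequence(seq)
        for m in sample.motion_mask:
            assert not m.any()

    def test_regeneration_is_deterministic(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        for out in (a, b):
            generate_dataset(out, scenarios=["S0-tissue"], n_sequences=1, n_frames=3, seed=9)
        assert (a / "manifest.yaml").read_text() == (b / "manifest.yaml").read_text()
        seq = yaml.safe_load((a / "manifest.yaml").read_text())["sequences"][0]["name"]
        for sub in ("depth", "left", "mask"):
            for fa in sorted((a / seq / sub).glob("*")):
                fb = b / seq / sub / fa.name
                assert fa.read_bytes() == fb.read_bytes()

    def test_round_trip_preserves_geometry(self, tmp_path):
        out = tmp_path / "ds"
        generate_dataset(out, scenarios=["S0-tissue"], n_sequences=1, n_frames=3, seed=4)
        seq_dir = next(p for p in out.iterdir() if p.is_dir())
        sample = read_sequence(seq_dir)
        assert sample.n_frames == 3
        assert sample.scenario.name == "S0-tissue"
        # depth survives 16-bit quantization to its storage precision
        d = sample.depth[0]
        assert d.valid.any()
        assert d.depth[d.valid].min() > 0
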