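# dynvo — motion-aware stereo visual odometry for dynamic scenes

Estimating the 6-DoF motion of an endoscope from stereo video is hard
precisely where it matters: surgical scenes deform (breathing, pulsation,
manipulated tissue) and contain moving instruments, while classical visual
odometry assumes a rigid world. `dynvo` is a toolkit for studying this
problem end to end:

* a **weighted dense pose optimizer** — the relative camera pose
  `T_{t+1,t} ∈ SE(3)` between consecutive frames is estimated by minimizing
  a motion-weighted reprojection objective

  ```
  T* = argmin_T  Σ_{x∈Ω}  (1 − M(x)) · r(T, x)²,
  r(T, x) = √(1/HW) · ‖ π( T · π⁻¹(D_t(x), x) ) − (x + F_fwd(x)) ‖₂
  ```

  where `π`/`π⁻¹` are the pinhole projection and back-projection, `D_t` is
  stereo depth (mm), `F_fwd` the forward temporal flow, and `M ∈ [0,1]` a
  per-pixel **motion probability** whose complement `W = 1 − M` down-weights
  dynamic pixels.  Minimization is damped Gauss–Newton
  (Levenberg–Marquardt) on the 6-dim twist, identity-initialized, capped at
  30 iterations.  Relative poses are chained into full trajectories.

* a **semi-synthetic dynamic-scene generator** — stereo sequences over a
  textured curved background with a known camera trajectory, composited
  with foreground layers that move rigidly (a "tool" patch driven by a
  homography sequence) or deform non-rigidly (a "tissue" patch driven by
  thin-plate-spline control points).  Depth, forward/backward temporal
  flow, stereo flow and motion masks are derived **in closed form**, so the
  geometric ground truth is exact.  Eight scenarios cross camera status
  (S0 moving / S1 still) with foreground content (tool+tissue / tool /
  tissue / static).

* **evaluation** — relative pose error (RPE, translation mm and rotation
  deg), absolute trajectory error (ATE, mm after rigid Umeyama alignment),
  and motion-mask IoU, plus a scenario-by-method benchmark matrix.

Motion probabilities can come from ground-truth masks, from external files
(e.g. a learned detector), or from the built-in training-free
flow-consistency detector.

## Worked example

Generate a moving-camera sequence with deforming tissue covering ~20% of
the frame, perturb the flow with 0.2 px noise (emulating a flow network's
association error), and compare unweighted ("naive") against ground-truth-
mask-weighted pose estimation:

```python
import numpy as np
from dynvo.synth import generate_sequence, with_flow_noise
from dynvo.motion import MotionProbabilityMap, weight_from_motion
from dynvo.pose import RelativePoseModel, chain_poses
from dynvo.metrics import rpe, ate

sample = generate_sequence("S0-tissue", n_frames=6, seed=42)
noisy = with_flow_noise(sample, 0.2, np.random.default_rng(0))

poses = {"naive": [], "weighted": []}
for t in range(sample.n_frames - 1):
    weights = weight_from_motion(
        MotionProbabilityMap(sample.motion_mask[t].astype(float))
    )
    for name, W in [("naive", None), ("weighted", weights)]:
        model = RelativePoseModel(
            noisy.flow_fwd[t], noisy.depth[t], sample.intrinsics, weights=W
        )
        poses[name].append(model.fit().pose)

for name, rel in poses.items():
    traj = chain_poses(rel)
    t_err, r_err = rpe(traj, sample.trajectory)
    print(f"{name:>9s}: RPE {t_err:.3f} mm / {r_err:.3f} deg, "
          f"ATE {ate(traj, sample.trajectory):.3f} mm")
```

Output:

```
    naive: RPE 0.393 mm / 0.400 deg, ATE 0.413 mm
 weighted: RPE 0.010 mm / 0.009 deg, ATE 0.013 mm
```

The deforming layer biases the unweighted fit by almost 0.4 mm per frame
pair; down-weighting the dynamic pixels brings the error down to the
flow-noise floor — a ~40x improvement.  `model.fit()` returns a results
object carrying the pose, per-pixel residuals, iteration diagnostics and a
`summary()` table; `.refine(mode="weighted")` re-optimizes on low-residual
inliers.

## Command line

```sh
dynvo gen   --scenario S0-tool-tissue --n-seq 8 --n-frames 30 --seed 0 --out data/
dynvo run   --seq data/seq_0000_S0-tool-tissue --motion flowcheck --out est.tum
dynvo eval  --seq data/seq_0000_S0-tool-tissue --est est.tum --report report.json
dynvo bench --seed 0 --n-seq 8 --n-frames 6 --out runs/bench
```

Datasets are written in plain formats (PNG images, 16-bit PNG depth,
Middlebury `.flo` flow, TUM trajectories, YAML metadata), so externally
computed inputs — flows, depths, motion maps — plug in unchanged.

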