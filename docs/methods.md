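# Methods

This note documents the models and procedures implemented in `dynvo`, the
design choices behind them, and what the synthetic experiments do and do
not demonstrate.

## Geometry and conventions

Pixels are 0-based and address pixel centers; coordinates are `(u, v)` =
(column, row) and may be sub-pixel everywhere.  The camera frame is +X
right, +Y down, +Z forward; the rectified rig's right camera sits at
`+baseline` along +X.  Depth and translation are in millimetres.  The
relative pose `T_{t+1,t}` maps frame-t camera coordinates into frame-t+1
coordinates; trajectories store camera-to-world poses with pose 0 the
identity reference, and chaining uses
`pose_k = pose_{k-1} ∘ T_{k,k-1}⁻¹`.

Stereo depth follows `Z = fx · b / d` with disparity `d = −Δx` of the
left-to-right stereo flow.  Disparities at or below 0.1 px are masked
invalid rather than converted (they would imply depths beyond
`fx·b/0.1`, numerically meaningless at this rig scale).

SE(3) is parameterized by twists `(ρ, φ)` through the closed-form
exponential/logarithm (Rodrigues with Taylor guards below 1e-10 rad; the
logarithm near rotation angle π warns and switches to the
symmetric-branch axis extraction).

## The weighted pose optimizer

Each frame pair defines a `RelativePoseModel` over the dense grids
(forward flow, depth, optional weights); `fit()` returns a
`RelativePoseResults` with the pose, per-pixel residuals, iteration
diagnostics and a text `summary()` — the model/results idiom familiar from
statistical modelling packages, chosen because a per-pair pose estimate
*is* a fitted model with residual diagnostics worth inspecting.

The objective is `Σ W(x) · r(x)²` over the usable pixel set Ω (finite
positive depth, flow target inside the image, transformed point in front
of the camera).  Weights multiply squared residuals; they are supplied as
`W = 1 − M` from a motion probability, as all-ones ("naive"), or from
files.  Two residuals are available:

* **reprojection-2d** (default): `√(1/HW) · ‖π(T π⁻¹(D_t(x), x)) −
  (x + F_fwd(x))‖`, in pixels;
* **alignment-3d** (ablation): `√(1/HW) · ‖T π⁻¹(D_t(x), x) −
  π⁻¹(D_{t+1}(x′), x′)‖` with `x′ = x + F_fwd(x)` and `D_{t+1}` sampled
  bilinearly, in mm.  Because it consumes depth at both frames linearly,
  it inherits depth noise directly, which is why it loses to the 2D
  residual under multiplicative depth noise (the suites confirm a ~35x
  RPE gap at 2% noise).

Minimization is Levenberg–Marquardt on the twist with a left-
multiplicative update `T ← exp(ξ̂) T`.  Defaults, all in
`ResidualOptions`: λ₀ = 1e-4, ×10 on a rejected step, ÷10 on acceptance;
stop at 30 iterations or a twist-update norm below 1e-8; identity
initialization; no robust kernel (an optional Huber is exposed but off).
Accepted steps never increase the objective by construction.  Jacobians
are analytic (`∂π · [I | −[X′]ₓ]`); a central-difference mode exists and
is held to the analytic one at 1e-5 relative accuracy in the tests.
Fewer than 6 usable pixels, or zero total weight, raises a
degenerate-problem error: with no rigid anchor visible the relative pose
is unobservable, and the estimator says so rather than returning noise.

**Inlier refinement.**  After a first fit, pixels whose unnormalized
reprojection error exceeds 3× the median are discarded and the fit is
re-run from the current pose — keeping the weight map on the inliers
("weighted" mode) or flattening it ("vanilla").  The 3×median rule is this
package's choice of a scale-free cut.  On the dynamic suites, weighted
refinement of the flow-consistency-weighted estimate lowers mean RPE
(≈0.36 → 0.19 mm) because the inlier cut removes the dynamic pixels the
soft detector under-weighted; refining a ground-truth-weighted estimate
is a fixed point.

## Motion probabilities

`weight_from_motion` forms `W = 1 − M` elementwise.  Sources of `M`:

* **ground truth** — the generator's binary masks;
* **external** — 8-bit PNG maps (value/255), so learned detectors plug in;
* **flow-consistency** (training-free stand-in for a learned detector):
  given a first-pass pose (a naive fit), the discrepancy
  `e(x) = ‖(x + F_fwd(x)) − π(T π⁻¹(D_t(x), x))‖` is mapped to
  `M = 1 − exp(−e²/2σ²)` with σ = 1 px by default; pixels where the check
  cannot be evaluated get `M = 1` (excluded).  IoU binarizes at 0.5, so
  the detector effectively sees displacements above ≈1.18 px.

A forward-backward consistency mask (`‖F_fwd(x) + F_bwd(x + F_fwd(x))‖ ≤
τ`, τ = 1 px, bilinear lookup) is available for occlusion handling of
real flows.  IoU is reported in percent with the both-empty case defined
as 100 (static scenes report no IoU at all); BCE clips probabilities at
1e-7.

**Known limitation.**  The flow-consistency detector relies on the naive
first pass being roughly right.  For *deforming tissue* this holds and
the detector reaches ~80% IoU on the dynamic suite.  For a *coherently
moving rigid tool* it can fail badly: the tool's motion field is itself
consistent with some camera pose at the tool's depth, the naive fit
partially absorbs it, and the residual-based detector then flags the
wrong region (IoU near zero on tool-only scenes).  This is a genuine
ambiguity of geometric consistency checks and the reason learned
detectors are used for instrument motion; the toolkit therefore treats
the detector as a pluggable stand-in, not a contribution.

## The synthetic scene generator

The generator emulates short endoscopic stereo clips while keeping every
geometric ground-truth channel exact:

* **Background**: a textured quadric surface — a shallow cavity whose rim
  approaches the camera (default 15 mm of relief at 40 mm lateral radius,
  randomly tilted up to 10°, nominal distance 60 mm).  Ray intersection
  is closed-form; an optional harmonic ripple is resolved by fixed-point
  refinement.  The relief matters: on a pure plane, small rotations and
  translations induce nearly indistinguishable flow, and the unweighted
  optimizer can absorb a constant-depth foreground motion at almost no
  background cost.  Textures are seeded multi-octave harmonic noise
  evaluated at the 3D intersection points, so left/right and successive
  frames are photometrically consistent by construction.
* **Camera**: S1 is exactly still; S0 integrates a smooth random twist
  velocity (cubic spline through waypoints) rescaled so no frame-to-frame
  step exceeds 0.8 mm / 0.5° (defaults).
* **Foreground layers**: alpha-masked patches at a constant depth drawn
  from [0.5, 0.8] × the minimum background depth (guaranteeing occlusion
  order).  The tool is an elongated convex polygon driven by a smoothstep
  interpolation from identity to a random bounded homography (±15°, ±60
  px, ±15% scale over a 30-frame reference span, so tool velocity is
  independent of clip length).  The tissue patch is a smooth
  Fourier-boundary blob driven by thin-plate-spline control points (5×5
  grid) following independent temporally-smoothed Gaussian random walks
  (RMS step 5 px/frame, clipped at 14 px excursion).  The step size was
  fixed so that the simulated deformation is resolvable by the σ = 1 px
  consistency detector — slower deformation is trivially invisible to any
  per-frame-pair instrument.
* **Composition** is back-to-front (background, tissue, tool).  A layer's
  placement composes (i) the exact plane-induced homography
  `K(R + t nᵀ/d) K⁻¹` accumulated over the camera's relative poses —
  "scene anchoring", which keeps non-moving layers geometrically
  consistent under camera motion — with (ii) the intrinsic warp in layer
  coordinates.  Depth on the support is the layer depth; stereo flow is
  the layer disparity; temporal flow is the anchoring flow plus the
  intrinsic displacement; the motion mask is the union over moving layers
  of pixels with intrinsic displacement above 0.1 px in the frame pair.
  Alpha is binary for all ground-truth channels; appearance is sampled
  bilinearly.

Because flow is *defined* as `π(T π⁻¹(x, D)) − x` on rigid content, the
estimator's residual at the generating pose is identically zero there —
the generator and estimator agree on the geometry to machine precision,
which the acceptance checks verify (< 1e-6 everywhere rigid).  For moving
tissue the inverse warp uses a backward-fitted TPS, exact at the controls
but approximate between them; the affected pixels are precisely the
masked ones, so the approximation never touches a rigid-pixel guarantee.

**What the generator does not model**: photorealism, specularity, smoke,
real instrument/organ appearance (textures and silhouettes are
procedural), layers with internal depth structure (each layer is a
constant-depth overlay), flow estimation error structure beyond iid
Gaussian noise, and occlusion-aware flow at layer boundaries.  Passing
the suites therefore demonstrates correctness of the geometry, the
optimizer and the weighting logic under controlled conditions — not
performance on real surgical video.

## Evaluation

RPE at frame delta 1: for each pair, the error motion
`E_i = rel_gt⁻¹ ∘ rel_est`; translation error `‖t(E)‖` (mm) and rotation
error `arccos((tr R_E − 1)/2)` (deg, argument clamped), aggregated by the
mean.  ATE: RMSE of camera positions after closed-form rigid Umeyama
alignment without scale (degenerate all-identical estimates skip the
rotation fit).  These are the standard trajectory-benchmark definitions;
the tests pin them to an independently coded quaternion/SVD reference at
1e-6.  Reports aggregate per scenario; static-content scenarios omit IoU.

## Study conditions and problem sizes

The default rig is 192×144 px, fx = fy = 160 px, 4.2 mm baseline — an
endoscope-like ~62° horizontal field of view scaled to desk-size grids.
Property suites use 20 sequences × 6 frames per condition; flow noise is
0.2 px iid Gaussian, depth noise 2% multiplicative where stated; the
benchmark matrix runs 8 scenarios × {naive, gt, flowcheck, rf.W, rf.N,
res.3D}.  One master seed drives every draw (per-sequence streams derive
from (seed, index)), so suites are order-independent, individually
regenerable, and byte-identical across reruns.
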