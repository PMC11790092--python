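# Methods

This note documents the models, parameter choices, numerical details and
known limitations of `berry3d`.

## Camera model and conventions

The unified omnidirectional camera model (UOCM) composes two projections:
radial projection onto the unit sphere centered at the camera, then a
pinhole projection whose center is displaced by the dimensionless offset
`ξ ≥ 0` along the optical axis. Projection is
`p̃ = K(x + t_ξ‖x‖)/(z + ξ‖x‖)`; unprojection is closed-form,

    η = (ξ + √(1 + (1−ξ²)(‖m‖²−1))) / ‖m‖²,   ray = η·m − t_ξ,   m = K⁻¹p̃,

and returns a unit ray (depth is unobservable from one pixel). `ξ = 0`
degenerates exactly to the pinhole model; both limits are covered by tests.
A pixel is inside the field of view when the discriminant is non-negative
(zero counts as inside — a closed-set convention that simplifies mask
generation) and the recovered ray has `z ≥ 0` (180° lens).

Conventions used throughout:

* camera frame: `z` optical axis, `x` right, `y` down; world frame = camera
  frame of the first frame of the sequence (or video part);
* pixel (0,0) top-left, integer coordinates are pixel centers — this matches
  the bilinear-sampling convention of the warp;
* **depth is Euclidean range along the ray** (distance from the camera
  center), not the `z` coordinate. This makes `point = ray · depth` exact
  under the sphere model and matches the renderer's ray-casting depth;
* `T_{t→t′}` maps camera-frame-`t` coordinates into camera frame `t′`;
  cumulative poses compose as `T_{t+1} = T_{t→t+1} ∘ T_t` with `T_1 = I`.

Calibration (`fx, fy, cx, cy, xi, height, width`) is an input; estimating it
is out of scope. No default is claimed to be any particular lens's true
`ξ`; the synthetic camera uses `ξ = 0.9`, typical of ~180° fisheyes.

## Differentiable view synthesis and losses

The warp unprojects each valid target pixel to a unit ray, scales it by the
depth, applies the relative pose, and re-projects through the UOCM; the
source frame is bilinearly resampled at the resulting continuous
coordinates. Pixels are excluded from every loss term (rather than
border-clamped) when they leave the source field of view or end up behind
the source camera: a ~180° frame has a large invalid region and clamping
would fabricate gradients.

The photometric error is `pe = (α/2)(1 − SSIM) + (1−α)L1` with `α = 0.85`
(the convention of the monocular-depth lineage; exposed in `LossWeights`),
SSIM computed with a 3×3 mean-pooling window, constants `C1 = 0.01²`,
`C2 = 0.03²` on [0,1] intensities, reflect padding. Both terms average over
color channels. The usable mask is eroded by one pixel so no 3×3 window
reads an invalid cell; the masking is verified by NaN-poisoning tests. The
reprojection loss **sums** the two source terms (`t−1`, `t+1`) — the printed
form of the objective — rather than taking the per-pixel minimum used by
some related methods.

The smoothness term penalizes forward differences of the mean-normalized
inverse depth `d* = (1/D)/mean(1/D)` (normalization is over the valid mask;
"normalized" is not given a formula in the source description, division by
the spatial mean is this package's choice), weighted by `exp(−|∂I|)` with
image gradients averaged over channels.

All of this is built on `berry3d.autodiff`, a small reverse-mode engine on
numpy arrays (elementwise ops, reductions, matmul, conv2d via im2col,
nearest upsampling, reflect padding, bilinear grid sampling). Every op has
an exact analytic backward pass checked against central differences. The
loss is piecewise-smooth: it is non-differentiable exactly on bilinear
knots (integer warp coordinates) and where mask membership flips; gradient
tests therefore evaluate at generic points away from those sets.

## Networks and training

* Depth: encoder-decoder with skip connections and multi-scale side
  predictions. Default widths (32, 64, 128, 256, 512, 512, 512) with 4 side
  scales follow the DispNet family; the `tiny` configuration
  (16, 32, 64, 128; 2 scales) is for 64×64 CPU runs. Prediction layers use
  `1/(α·sigmoid+β)`, `α=10`, `β=0.01`, bounding depth to ≈(0.0999, 100).
  Prediction layers are zero-initialized with the bias set so the untrained
  network emits a constant plausible depth (`init_depth`, default 5; 3 in
  the tiny config).
* Pose: seven stride-2 convolutions over the channel-concatenated views, a
  1×1 head with `6(N−1)` channels, global average pooling; outputs are
  3 Euler angles (intrinsic XYZ, radians) + 3 translations per source view.
  The head is zero-initialized (untrained prediction = identity pose). For
  long large-scale trainings the angle outputs are scaled by 0.01 before
  conversion, a standard stability device; the tiny configuration predicts
  raw radians, because with an adaptive optimizer the per-step parameter
  movement is of order the learning rate and scaled outputs would make
  realistic inter-frame rotations unreachable within a few hundred steps.
* `d_min = 1`, `d_max = 100` are applied as a hard clamp on predicted depth
  before warping. Note the activation already bounds depth to (0.0999,
  100): with the defaults only the lower clamp can engage. Both printed
  statements are honored; the tension between them is resolved by keeping
  scene depths inside [1, 100].
* Optimizer: Adam. Full-scale default learning rate 1e-4 for ten epochs (the
  cited implementation lineage's defaults). The scaled-down run
  (`TrainingConfig.tiny()`) uses a two-speed schedule — depth 1e-3, pose
  1e-2 — because pooled pose gradients are weaker than per-pixel depth
  gradients and the depth network otherwise absorbs all early error;
  smoothness weight 0.02 (vs default 1e-3) to suppress depth noise a short
  run cannot average away; the loss is applied at 2 scales (the coarse
  scale enlarges the photometric basin). Sequence ends are skipped (a
  triplet needs both neighbors). Training aborts on a non-finite loss; a
  source warp with no valid overlap is skipped for that step.
* Checkpoints are npz archives with the config embedded; reloads are
  bit-exact. Seeded runs reproduce loss histories bit-exactly on CPU.

## Berry tracking

2D berry centers are an input (the instance-segmentation stage that would
produce them on real imagery is external). Depth at a sub-pixel center is
bilinearly sampled. The matching gate defaults to 1.5× the median
nearest-neighbor spacing of the current frame's lifted berries — an absolute
threshold would be meaningless at the arbitrary scale of a monocular
reconstruction. Matching is restricted to consecutive frames, and a pair
must be mutual (each the other's nearest neighbor, forward and backward).
Tracks need ≥ 5 consecutive observations; survivors carry their mean world
position as the bundle-adjustment initialization.

A lifted center is the berry's *front surface* point (the depth map stores
surface range), which sits about one berry radius in front of the center
and varies slightly with viewing direction. This is inherent to
centroid-plus-depth lifting; it bounds how small the bundle-adjustment
objective can get on otherwise perfect inputs and is accounted for in the
tests.

## Bundle adjustment

Objective: `Σ_{t,j} Huber_δ(‖⟨x_{t,j}⟩ − ⟨R_t w_j + t_t⟩‖)` with `δ = 0.1`
(unit-sphere residual units; residual norms live in [0, 2]). `T_1` is
pinned to the identity. The inner solver is damped least squares (scipy
`least_squares`, trust-region reflective) on the reparameterized residual
`g(r) = r·√(2·Huber(‖r‖))/‖r‖`, whose half squared norm equals the Huber
objective exactly — this applies Huber to the *norm* of each 3-vector
residual, as written, not per component. Rotations are optimized as
rotation-vector increments about the current estimate (no Euler
singularities). Alternation runs pose-only then point-only half-steps, 10
rounds by default or until the relative objective change falls below 1e-8;
accepted steps never increase the objective.

Because `⟨·⟩` cancels any global rescaling of `{w_j, t_t}`, the objective
has an exact scale null direction. Joint optimization wanders along it — on
the standard perturbed instance (20 cameras, 50 points, 2° rotation noise,
translation noise 2% of the orbit radius, point noise 2% of the bunch
diameter, exact observations) the joint solver changes the scale metric
(mean point distance to centroid) by orders of magnitude while driving the
objective to zero. Alternation anchors scale in whichever block is fixed
and keeps the metric within a fraction of a percent. This contrast is the
core reason the pipeline uses the alternating solver.

## Synthetic scenes — what they emulate and what they do not

The renderer ray-casts spheres analytically, so depth, per-pixel 3D
correspondences, berry identities and visibility are exact to float
precision — the point of the generator is to be an oracle, not to be
photorealistic. It emulates the conditions the method is designed for:
textureless quasi-spherical berries in a downward-tapering crowded cluster,
Lambertian shading under a fixed light, a hand-held close-range orbit
(seeded positional jitter, every frame fixating the bunch centroid), a
~180° camera, and an enclosing background surface standing in for the
canopy a short distance behind the bunch (≈3× the orbit radius — field
scenes are enclosed, not open, and a very distant empty background would
dominate the image with pixels whose depth is photometrically almost
unconstrained). A mild 3D value-noise modulation is attached to all
surfaces: perfectly constant albedo gives the photometric loss degenerate
flat minima, and surface-attached noise stays consistent across views,
unlike screen-space noise.

Fixture presets (`FIXTURE_PRESETS`): `orbit-small` — 128×128, 30 berries,
20 frames over 90°, orbit radius 3.0, used for geometry/warp/matching
oracles; `train-tiny` — 64×64, 25 berries, 60 frames over 180° (≈3°/frame,
a 30 fps hand-held orbit subsampled in time), orbit radius 2.6, framing
scale 2.8 so the bunch fills most of the frame as the real close-range
captures do, texture amplitude 0.35.

What passing these tests does **not** show about real data: no leaves,
stems or specular highlights; no lighting changes, motion blur or rolling
shutter; berry detections are exact projections rather than segmentation
centroids with detector noise; and the tiny training run demonstrates that
the training signal is correct and informative at small scale, not the
accuracy of a fully trained field model.

## Numerical choices and degenerate inputs

* Round-trip angular errors are measured with `‖a×b‖` — `arccos` of a dot
  product cannot resolve angles below ~1e-8 in float64.
* Warp validity requires the whole 2×2 bilinear footprint inside the source
  FoV mask and the transformed point in front of the virtual pinhole
  (`z + ξ‖x‖ > 1e-9`); invalid resampled cells carry NaN sentinels.
* Empty valid masks raise a no-overlap error in direct loss evaluation; in
  training, a single empty warp term is skipped (the other source still
  constrains the step) and only all-empty losses raise.
* Ties in nearest-neighbor queries follow the KD-tree's deterministic
  ordering; no randomness is involved at matching time.
* The bunch generator retries rejected placements a bounded number of times
  and raises on infeasible packings.

## Known limitations

* Monocular scale is arbitrary; the alternating scheme preserves the
  *initial* scale, it does not recover a metric one.
* No occlusion reasoning in the photometric loss; occluded pixels
  contribute noise (the oracle tests exclude them via the renderer's
  covisibility mask).
* Tracking has no re-identification: an occlusion gap splits a berry into
  two tracks.
* Per-part reconstructions are not merged into a whole-bunch model.
* The training loop is CPU numpy; it is sized for small fixtures and
  method validation, not for training on large video corpora.
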