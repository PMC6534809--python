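# Methods

This note documents the models, numerical choices and limitations of
`leafps`, in the order data flows through the pipeline.

## Coordinate and unit conventions

Images are indexed (row, col), 0-based, origin top-left. The camera
frame has x to the right (columns), y down (rows), z toward the camera,
so an upward-facing surface has normal (0, 0, 1) and surface inclination
is arccos nz. Angles are serialized in degrees everywhere; radians are
internal only. Greyscale images are normalized to [0, 1] on read by
dividing by the dtype maximum. Lengths are millimetres; the camera is a
single scale factor (default 170 mm / 2048 px ≈ 0.0830 mm/px, a
17 × 17 cm field of view) under an orthographic approximation —
perspective effects over a ~40 cm working distance and a few mm of
relief are below the other error sources considered here.

## Lighting model

Lights are distant and directional: `build_rig(n, tilt, azimuth0)`
places n unit vectors at equal 360/n-degree azimuth spacing, each
inclined `tilt` from the optical axis (default: 8 lights, 45° spacing,
30° tilt). Near-field falloff over the working distance is not
modelled; a per-light scalar gain absorbs first-order intensity
differences between LEDs. Rigs must have at least 3 lights and a
rank-3 direction matrix.

## Synthetic scenes

The generator exists to provide exact, controllable ground truth, not
photorealism.

- **Flat targets**: a square planar patch of true surface area A tilted
  by θ; the rendered footprint is foreshortened by cos θ and the
  ground-truth normal is constant. The patch is centred on the image
  centre; validation uses odd-sized frames so that centre is a pixel
  centre, which removes a systematic one-pixel-row overcount in the
  rasterized footprint.
- **Sphere caps**: height √(R²−r²) − (R−h) with analytic normals;
  closed forms πh(2R−h) (footprint) and 2πRh (surface) make them the
  oracle for curved-surface area and for depth integration.
- **Rosettes**: n equal-azimuth leaves, each an ellipse (semi-axes a, b)
  on a narrow flat petiole. The blade is rigidly inclined by the nastic
  angle β(t) = baseline + amplitude·cos(2π(t − phase)/period) and carries
  an elliptic-paraboloid dome (height 0.15·b) so it is convex from above
  — consequently its *measured* mean inclination exceeds β and is > 0
  even at β = 0, as real leaf blades are. Blade planform area grows as
  A₀e^(rt) (semi-axes scale as e^(rt/2)); the petiole scales alike.
  Defaults describe a young rosette sampled every 30 min under a 12:12 h
  light:dark cycle: 3 leaves, blade 2.5 × 1.5 mm semi-axes, petiole
  2.5 mm (blade:petiole chord ratio 2:1), baseline 25°, amplitude 10°,
  period 24 h, peak 5 h after dusk, growth 0.01 h⁻¹ (~27%/day).
  Per-frame metadata records each leaf's closed-form planform area, its
  numerically exact 3D surface area, the nastic angle and its
  visibility; fully occluded leaves and border-clipped frames add
  warning records.

Rendering applies the Lambertian model I = g·ρ·max(0, n·l) per light.
Only attached shadows (n·l ≤ 0) are modelled; cast shadows (one leaf
shading another) are not — the renderer is an oracle, and omitting them
keeps every rendered pixel exactly consistent with the stored normals.
Gaussian noise (default sd 0.01 of full scale, single integer seed) is
added after shading; output is clipped to [0, 1 + 5·sd]. Rasterization
is centre-sampled with no anti-aliasing so pixel counts are exactly
reproducible. Real data differ in ways the generator deliberately does
not emulate: specular/subsurface deviations from Lambertian reflectance,
cast shadows, soil background texture, and leaf shape irregularity —
passing tests bound algorithmic error, not these physical effects.

## Normal estimation

Per pixel, measurements above the shadow threshold (default 0.02 of
full scale — excluding near-zero samples is the standard remedy for
attached shadows) are kept, each divided by its light gain, and
ρ**n** is solved by least squares; pixels sharing a usable-light
pattern are solved in one batched pseudoinverse. Optionally
(`discard_extremes`, rigs with > 4 lights) the brightest and dimmest
usable sample per pixel are dropped as a guard against residual
highlights and soft shadows; both paths are exposed because neither is
canonical. Pixels with fewer than 3 usable lights or albedo below a
floor (10⁻³) are invalid; solutions facing away from the camera are
flipped only if the flipped normal explains the measurements at least
as well, else invalidated. Invalid pixels carry the placeholder
(0, 0, 1) with zero albedo so no NaN ever reaches a trait sum.

## Depth integration

Gradients p = −nx/nz, q = −ny/nz (nz clamped at 0.05 to bound the 1/nz
amplification near silhouettes) are integrated over the bounding box of
the valid region by minimizing the discrete functional
Σ(Δx z − p̄)² + (Δy z − q̄)², with gradient samples averaged onto
staggered midpoints. The default `frequency` method solves the
resulting Neumann-Laplacian normal equations with a type-II cosine
transform (equivalently, a frequency-domain solve on the mirror-padded
domain); `poisson` solves the identical equations by sparse LU, an
algebraically independent cross-check. Natural boundary conditions
mean tilted planes are recovered exactly; output is zero-meaned over
the valid region, so depth is relative. Limitation: gradients are
zero-filled on invalid pixels inside the bounding box, which distorts
the solution when the valid region is far from box-filling (e.g. a
rotated rectangle); traits therefore never use the depth map —
inclination always comes from the normals directly.

## Traits

- 2D projected area = foreground pixel count × px². 3D area =
  Σ px² / max(nz, 0.05); invalid pixels contribute the flat px²
  fallback and are tallied in an `invalid_fraction` (warning above
  50%). By construction 3D ≥ 2D area.
- Shape descriptors on the filled foreground union: circularity
  4πA/P²; compactness A / convex-hull area (the hull-ratio convention
  for rosettes; it tracks petiole elongation); diameter of the minimum
  enclosing circle (stable under concavities, unlike max Feret);
  perimeter as the marching-squares contour length after
  Douglas–Peucker simplification (tolerance 1 px) — raw staircase
  contours overestimate smooth boundaries by ~6%, the simplified
  polygon is within 1% on discs and squares. Hull and enclosing circle
  are taken over boundary-pixel corners so a w-pixel square measures w,
  not w−1. These descriptor identities hold to discretization
  tolerance (tests allow 0.2%–5% depending on the quantity).
- RER uses natural-log areas over a sliding window (default 4 h);
  windows spanning a lights-on/off transition are excluded rather than
  averaged across phases.
- Convexity is the negated divergence of (nx, ny) after optional
  Gaussian smoothing: negative over domes, positive over bowls, zero on
  planes.

## Tracking

The four-parameter scheme — span 10, search radius 30 px, frame memory
3, minimum track length 100 — is implemented as constant-velocity
prediction (mean per-frame velocity over up to `span` recent steps)
with nearest-neighbour gating, deterministic tie-breaks (smaller track
id, then smaller label), and an optional globally-optimal per-frame
assignment. Unmatched observations open tracks; tracks unseen longer
than the memory close; the length filter counts total frames seen (not
consecutive). Identity through leaf crossings relies on the velocity
prediction; simultaneous overlap of instances in the label map itself
is the segmenter's problem, not the tracker's. Manual correction of
rare identity errors is supported by applying a (frame, old→new) edit
table after tracking rather than interactively.

## Blade/petiole analysis

Opening with a disc (radius 3–11 px, auto-selected as
clip(round(0.3·√area/2), 3, 11)) removes structures narrower than
~2·radius; the blade is the largest connected component of the opening
and the petiole the exact remainder. P_B is the centroid of the
blade–petiole contact band, computed against the petiole's largest
connected component; a petiole whose largest piece is under 5 px is
treated as absent (opening residue), in which case P_B falls back to
the blade boundary pixel nearest the rosette origin. P_T is the blade
pixel farthest from the origin. Blade and petiole lengths are the
straight chords P_B–P_T and P_O–P_B (not geodesics over the 3D
surface); the blade:petiole ratio is flagged undefined when the petiole
is absent. Blade inclination is offered both as the mean over the
blade and as the mean along the rasterized P_B→P_T line; the line
method falls back to the mean with a warning when landmarks degenerate.

## Rhythm analysis

Series are detrended by subtracting a centred moving average whose
window (default 24 h) spans exactly `window/Δt` samples — one full
period of a sampled oscillation then cancels identically — with
shrinking windows at the edges, followed by mean alignment to zero.
Harmonic regression (3 harmonics) is scanned over periods 18–34 h in
0.05 h steps with bounded local refinement to sub-grid precision.
Amplitude is that of the fundamental (half peak-to-trough); phase is
the fundamental's peak time after dusk (lights-off), modulo the period,
with a dawn reference available. Series with variance below 10⁻¹⁰
return an explicit arrhythmic result (amplitude 0, period NaN) rather
than raising. At least two full cycles of data are required. Goodness
is the residual variance fraction.

## Segmentation metrics

Best dice BD(X→Y) averages, over instances of X, the best dice overlap
with any instance of Y; SBD is the minimum of the two directions, FBD
the dice of binarized foregrounds. Both are invariant to label
permutation; SBD ≤ FBD does *not* hold in general and is not asserted.
Scores are reported per frame and as unweighted means over a series.
Instances with zero pixels are dropped before scoring.

## Pipeline and determinism

`run_pipeline` executes render → normals → traits → track → leaves →
rhythm → evaluate on a synthetic experiment described by a single JSON
config; every output directory carries the config hash and seed, and
all randomness derives from that one seed, so identical config + seed
reproduce CSV outputs byte for byte (fixed float formatting, no
timestamps). Stages communicate in memory within a call; requesting a
stage without its prerequisite raises an error naming the missing
stage. The default experiment spans 72 h at 0.5 h (145 frames) on a
161² image at 0.2 mm/px — three diel cycles, enough for detrending plus
a two-cycle fit, with the rosette inside the frame throughout; the
flat-target validation sweep uses 449² frames at the default camera
scale. Problem sizes in the test suite follow the same choices.

## Known limitations

- Uncalibrated or near-field photometric stereo, non-Lambertian
  reflectance fitting and light-position refinement are out of scope.
- Depth from integration is relative (arbitrary offset) and degrades
  when the valid region fills its bounding box poorly.
- The tracker has no appearance model; it will swap identities if two
  leaves' centroids coincide in position *and* predicted velocity.
- Rosette leaves in the generator do not bend along the petiole, droop,
  or twist; occlusion occurs only when leaves geometrically overlap.
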