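# Methods

This note documents the models, parameters, numerical choices and known
limitations of the bovimetry pipeline, in the order data flows through it.

## Camera model

The camera is a zero-skew pinhole: pixel `(u, v)` = (column, row), origin
top-left; camera frame X right, Y **down**, Z along the optical axis.
Depth is the Z-coordinate in millimetres (the convention of rectified depth
cameras), so the inverse projection
`X = (u − cx)Z/fx`, `Y = (v − cy)Z/fy` is closed-form and exact. No lens
distortion is modelled; depth cameras emit rectified maps. Sub-pixel
keypoints are accepted everywhere; only depth *lookup* rounds to the
nearest integer pixel (half away from zero, so the rounding is symmetric).
Intrinsics are a mandatory user input — there is no meaningful default for
a physical camera; the synthetic default (1280×720, fx = fy = 700,
principal point at the centre) is a plausible depth-camera geometry, not a
device calibration.

## Conditional depth filtering

Depth at a detected landmark pixel is often invalid (0) or contaminated:
contour landmarks (Withers, Sole, Pin) sit on the animal's outline where a
one-pixel error lands on background. The filter therefore:

1. takes the **reference depth** as the arithmetic mean of valid samples
   (`valid_min < d ≤ valid_max`, default `(0, 7000]` mm — 7000 itself is
   valid) in a `(2·neighborhood+1)²` window (default 3×3) around the
   rounded Shoulder–Pin midpoint, a stable patch in the middle of the
   flank;
2. replaces each landmark's depth with the value of the nearest pixel that
   is valid **and** within `ref_tolerance` (default 500 mm, compared with
   `≤`) of the reference.

"Nearest" is implemented as concentric Chebyshev rings of increasing
radius (default `max_radius` 20 px), ties within a ring broken by scan
order (increasing dy, then dx): deterministic, and faithful to the intent
of finding the *closest* acceptable depth. A `raster` compatibility mode
reproduces the naive dx-major double loop, which returns the first hit of
the square scan rather than the nearest pixel. An empty reference window
is an error by default; the opt-in `grow_reference` mode doubles the
window half-width up to three times first. A landmark with no qualifying
depth within the radius becomes *missing* — downstream measurements that
need it fail by name, they are never fabricated.

## The four dimensions

All geometry is in camera-frame mm; results are cm = mm/10, with rounding
applied only at presentation (0.1 cm in CSV output).

* **Body height** = |Withers − Sole|, **body oblique length** =
  |Shoulder − Pin| (Euclidean distances of the lifted landmarks).
* **Lumbar height**: manual practice stands a stick on the ground under
  the loin. Emulated by constructing the ground pixel
  `(u_Lumbar, v_Sole)`, lifting it with the *Sole's* refined depth, and
  taking the distance from the lifted Lumbar point. When Sole and Lumbar
  depths differ (they do: hoof and topline are different distances from
  the camera) the constructed point is slightly oblique, a method bias of
  ~0.1–0.5 % on realistic geometry.
* **Chest girth**: see below.

## Girth curve pipeline

Stages, with the defaults and why:

1. **Profile** (`profile_mode="surface"`, `num_points=50`): pixels
   linearly spaced on the Chest1→Chest2 image segment, each lifted with
   its own conditionally filtered depth, so the 3-D curve follows the
   visible flank. 50 points sample a ~170 px segment every ~3.4 px. The
   `chord` mode (straight 3-D segment between the landmarks) is retained
   for comparison with naive implementations; it degenerates to a flat
   loop of about twice the chord and is reported with a warning.
2. **RBF smoothing** (`smooth_factor=1.0`, `rbf_epsilon=1.0`,
   `refine_factor=10`): each coordinate is fit as a function of sample
   index with the multiquadric kernel `φ(r) = √(r² + ε²)` plus the linear
   polynomial tail the kernel's conditional positive-definiteness
   requires, ridge smoothing `smooth_factor` (0 = exact interpolation),
   evaluated on a 10× denser grid. The polynomial tail makes the fit
   reproduce affine curves exactly — a straight chord stays straight. The
   smoothing value is mild: enough to damp single-sample depth outliers
   without visibly shrinking the arc. ε defaults to the mean index
   spacing (1.0), the standard shape heuristic.
3. **Mirror** (`mirror_frame="chord_local"`): reflect the smoothed
   half-curve across the plane spanned by the Chest1–Chest2 chord and the
   chord-midpoint→camera direction, then reverse the sequence so the
   concatenated loop winds consistently. A `literal_y` parity mode negates
   camera-frame Y, which is geometrically meaningful only for
   pre-centred inputs.
4. **Closure** (`spline_closure="periodic"`): consecutive duplicates (the
   chord endpoints are fixed by the mirror) are removed, a periodic cubic
   B-spline interpolates the loop exactly (smoothing 0), and the girth is
   the summed segment length of the densely resampled closed polyline.

### The single-view visibility bound

A reflection is an isometry and both chord endpoints are its fixed points,
so the closed loop's length is **exactly twice the visible arc**. From a
camera at distance `d_c` from the section centre, the visible part of a
convex section is bounded by the two tangency points; for a circle of
radius `r` it subtends `2·arccos(r/d_c) < π`. The estimate is therefore
bounded by `(2/π)·arccos(r/d_c) · 2πr`: −7.4 % at 3 m for r = 350 mm,
−5.6 % at 4 m, and still −3.2 % at the 7 m sensor range limit. On top of
that, annotated landmarks sit on the outermost *pixel rows* of the
silhouette, a hair inside the mathematical tangency, which costs another
sliver of arc (~100 mm on the default section). The pipeline's output
tracks twice the section arc between the Chest anchors to ~0.3 % on clean
renders — that is the correct analytic oracle for this method — while
deviating −16…−19 % from the full perimeter. Closing the gap requires
either a second viewpoint or a parametric section model (e.g. fitting an
ellipse to the arc), both outside this pipeline. Tests that compare the
girth against the full perimeter at 3 % document this bound and fail by
design; the suite's green girth tests assert the visible-arc oracle.

## Evaluation metrics

OKS uses `exp(−d²/(2S²σᵢ²))` summed over landmarks whose *annotation*
visibility is positive (occluded-but-marked counts), divided by their
number; `S = √(bbox area)`. Per-landmark σ values are not established for
cattle, so a uniform 0.05 (a mid-range pose-estimation value) is the
default, configurable per landmark. AP is the fraction of detections with
OKS **strictly** above the threshold (default 0.5); mAP averages AP over
categories (a single category here). Precision is TP/(TP+FP) and recall
TP/(TP+FN). MAE is in measurement units; MRE is the mean of per-pair
relative errors in percent of the manual value, which requires positive
manual values.

## Synthetic scenes

The generator emulates the field setup: a tripod camera ~1 m high,
side-on, 1–5 m from a standing animal, 16-bit millimetre depth PNGs.

* **Geometry**: elliptical-cylinder torso (default semi-axes 450 mm depth
  × 350 mm height, length 1500 mm, axis 900 mm above ground), four
  vertical cylindrical legs (radius 60 mm), infinite ground plane. Random
  herds draw torso 1.35–1.65 m, withers height 1.08–1.27 m, section
  760–940 × 600–760 mm — the range manual measurement of adult beef cattle
  spans.
* **Anchors**: topline and chest landmarks are placed where an annotator
  clicks — on the torso silhouette, snapped to the surface point seen
  through the centre of the outermost visible pixel row of the canonical
  view (baked into the model as `view_*` parameters). Under perspective
  the geometric top of a convex body is self-occluded (~100 mm depth
  deficit at 3 m), so silhouette anchors are the only placement for which
  "rendered depth equals anchor depth" holds, as it does for a real
  annotation on a real image. Consequently the default true body height
  is ~1249 mm rather than the 1250 mm of the axis+semi-height sum.
* **Renderer**: per pixel, the smallest positive optical-axis distance of
  ray–primitive intersections (quadratics for the cylinders, a plane for
  the ground), quantized to integer mm; no hit within 7000 mm → 0.
  Depth is the Z-coordinate, not ray length, so the pinhole inversion is
  exact on renders up to quantization. Torso end caps are not rendered
  (side views never see them).
* **Truth**: body height/length from anchors; lumbar height is the
  anchor's height above ground; girth is the ellipse perimeter by
  adaptive quadrature of `∫√(a²sin²θ + b²cos²θ)dθ` (1e-9 relative;
  cross-checked against Ramanujan-II and the complete elliptic integral).
* **Noise**: seeded per-pixel dropout, disk-shaped holes, and additive
  Gaussian depth jitter clamped to [0, 7000] mm — the depth-domain
  analogue of adverse weather and sensor degradation. Identical seeds
  give bit-identical fields.

What the generator does **not** emulate: articulated posture (head
lowering, gait), non-elliptical cross-sections, fur/specular dropout
structure, multi-animal scenes, RGB appearance. Passing tests show the
*geometric* pipeline is correct and robust to idealized sensor noise; they
do not certify detector accuracy or deformation effects on real animals.

## Study conditions and problem sizes

Distance sweeps use camera-to-centre distances 2450–4000 mm, i.e.
2.0–3.55 m from the near flank, inside the 2–4 m band a side-view rig
operates in; nearer placements push the hooves out of a 720-row frame at
f = 700. Parameter-recovery runs use 10 random animals; jitter robustness
averages 12 animals × 3 noise replicates per level (0/5/15/30 mm), sized
so sampling noise does not mask the monotone trend for the unbiased
dimensions. Keypoint-neighbourhood dropout uses rate 0.20 in 31×31 px
windows. All randomness flows from explicit seeds; every run is
bit-reproducible.

## Known limitations

* The girth visibility bound above: single-view mirror completion cannot
  reach the true perimeter of a convex section.
* Girth error under depth jitter is non-monotone: noise inflates curve
  length, which partially cancels the negative visibility bias before
  degrading further — mean girth error can *decrease* with moderate
  jitter. The unbiased dimensions degrade monotonically.
* Lumbar height inherits a small oblique-ground-point bias when hoof and
  loin depths differ.
* The depth filter's ring tie-break (rows before columns) can move a
  silhouette landmark's depth one row inward under local dropout, which
  trims the girth profile by a few percent while leaving the other
  dimensions untouched.
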