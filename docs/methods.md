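# Methods

## Problem and scope

`topmorph` measures animals imaged from directly above. Two inputs drive
everything: a per-animal binary mask (from any instance segmenter, or
from the built-in classical one) and, optionally, a depth map from a
downward-looking depth camera (per-pixel camera-to-surface distance in
meters, zeros marking dropped readings). From these it computes the
standard top-view morphometric feature set — dorsal length, abdominal
width, area, centroid and rotated-box coordinates in 2D; average height,
height at the centroid, and volume in 3D — and evaluates detection
quality with average precision at fixed IoU thresholds.

## Coordinate, unit, and angle conventions

* Pixels are addressed 0-based as `(row, col)`, row increasing downward.
  In the feature table, columns ending in `_x` are ROW coordinates and
  `_y` are COLUMN coordinates. This inverts the everyday x/y reading and
  is stated here prominently for that reason.
* The rotated rectangle encloses **pixel centers**: a run of `w` pixels
  has extent `w − 1`. This makes degenerate inputs exact (one pixel is a
  zero-size box) and lets brute-force oracles agree to machine
  precision; it differs by about one pixel per side from a pixel-area
  convention, which matters only for objects a few pixels across.
* Angles are measured counterclockwise from the column (horizontal)
  axis in the `(x=col, y=row)` frame and reduced to `[0, 180)` degrees.
* The pixels-per-meter scalar `ppm` (default 1) divides lengths once and
  areas/volumes twice. Coordinates (centroid, box corners) are
  locations, not sizes, and are never divided by `ppm`.

## Minimum rotated rectangle

The minimum-area rectangle over the foreground pixel centers is computed
by rotating calipers: the convex hull is built first, and because the
optimal rectangle has a side collinear with some hull edge, only hull-edge
orientations need to be searched. Degenerate masks (single pixel,
collinear pixels) return a zero-width rectangle instead of raising, so
batch runs never abort on a sliver. The table schema reports two corners
of the rotated box: `topleft` is the corner minimizing `row + col` and
`bottomright` the one maximizing it (ties to the smaller row), which
together with length/width/angle makes the box reconstructible.

A caveat worth knowing: the fitted **angle** is a sharp pose estimate
only for shapes with corners. For elliptical bodies, the area of the
circumscribed rectangle varies with orientation only as
`~((a² − b²)/ab)² · θ²/2` near the optimum, so a few pixels of
rasterization jitter can move the argmin by several degrees (measured:
mean ≈ 2°, worst ≈ 8° for a 50 × 25 px ellipse). Length and width are
unaffected (the caliper extents are flat functions of the same jitter).
When a precise orientation of a smooth body is needed, use the
second-moment (principal-axis) orientation instead; the test suite does
exactly that when checking phantom poses.

## Depth pipeline

Order of operations, applied to the raw depth grid:

1. **Hadamard masking** — elementwise product with the binary mask;
   background becomes exactly 0 (i.e. "missing").
2. **Zero fill** — every zero (masked background and sensor dropout
   alike) is replaced by the mean of the nonzero values.
3. **Gaussian smoothing** — standard deviation `gaussian_sigma`
   (default 1 px), reflect boundaries so constant fields are fixed
   points; `sigma = 0` is an exact identity.
4. **Height conversion** — `height = camera_to_ground − depth`, with
   `camera_to_ground` the depth reading over bare floor (default 2.5 m).
   The subtraction is the only reading under which the camera-to-ground
   distance is a meaningful calibration parameter and heights come out
   in meters.

Features are computed on the smoothed field, restricted to mask pixels:
`height_average` is the ROI mean, `height_centroid` samples the pixel
nearest the (fractional) centroid (exact halves round toward the smaller
index), and `volume` is the ROI height sum divided by `ppm²`.

Numerical consequences of the mean-fill rule worth knowing:

* Filling the background with the ROI-mean depth means heights outside
  the ROI are physically meaningless; they only influence results
  through smoothing at the ROI rim (a bias of order +1–2% on volume and
  mean height at `sigma = 1` for bodies ~50 px across).
* `height_centroid` is a single-pixel statistic: if the centroid pixel
  itself was a dropout, its filled (scene-mean) value is what gets
  sampled after smoothing, which can shift the reading by ~5% at 2%
  dropout. Averaged statistics are robust to this; the point statistic
  is not.

Depth files are comma-separated numeric grids, optionally with one
header row (auto-detected). Values above 100 trigger a warning that the
file is probably millimeter-scale (consumer depth sensors commonly emit
mm); a CLI flag `--mm` performs the conversion.

## Classical segmenter

`segment_classical` thresholds height above the floor (`min_height`,
default 0.1 m), labels 8-connected components (8-connectivity keeps thin
diagonal limbs attached), and drops components below `min_area_px`
(default 50 px) — which also removes isolated dropout pixels, whose zero
depth reads as a spuriously tall spike. The confidence score (fraction
of component pixels above `2·min_height`, clamped to `[0.05, 1]`) is a
deliberate heuristic for ranking, **not** a calibrated probability.
Instances are ordered by score, then larger area, then smaller
first-pixel index, making outputs deterministic.

Threshold selection rule: `min_height` should sit well above the sensor
noise floor (≥ 5 standard deviations) but as low as that permits,
because every extra centimeter of threshold excises the low outer rim of
the body and biases width and mean-height recovery. The recovery
experiments therefore use 0.05 m against 0.01 m noise; thresholding a
half-ellipsoid of apex `c` at height `t` retains exactly the fraction
`1 − (t/c)²` of its footprint, which quantifies the bias of any choice.

## Average precision

Matching is greedy in descending score order: each prediction claims the
unmatched ground truth of highest IoU if that IoU reaches the threshold;
each truth is used once; ties break toward the smaller truth index. AP
is the exact area under the right-max interpolated precision–recall
curve (`p̃(r) = max_{r′≥r} p(r′)`), i.e. all-point interpolation rather
than 11-point sampling — the continuous reading of the PR integral.
Datasets are scored per image and averaged with equal weight by default;
a pooled global ranking is available as an option. Evaluation accepts
overlapping predictions (real detectors emit them); only label-image
containers enforce disjointness.

## Synthetic phantoms

Animals are half-ellipsoid mounds: semi-axes `a ≥ b` (m) in the plane,
apex height `c`, pose angle θ, elevation
`h(u,v) = c·√(1 − u² − v²)` in the body frame. Every feature has a
closed form (length `2a`, width `2b`, area `πab`, volume `(2/3)πabc`,
mean height `2c/3`, apex `c`), verified once against numeric double
integration, so the whole pipeline can be validated without real data.
The depth render is `camera_to_ground − h` plus Gaussian sensor noise,
then uniform dropout zeros (noise before dropout; holes strike on and
off the animal, exercising the fill step in both regions). Generation is
bit-reproducible from an integer seed.

Footprint rasterization uses the **closed** region `1 − u² − v² ≥ 0`:
pixel centers exactly on the boundary belong to the body. Under the
pixel-center extent convention the open region would lose a full pixel
per side on axis-aligned bodies (48 px measured for a 50 px diameter);
the closed region is the faithful rasterization of the continuous body
and makes the canonical axis-aligned case exact. For generic poses a
residual raster bias of roughly half a pixel per side remains — about
−1% on a 50 px width at 100 px/m — which is part of the error budget
quoted below.

Default scene (the conditions used throughout the tests and the
acceptance script): 160 × 200 px grid at 100 px/m, camera 2.5 m above
the floor, one pig-sized animal (1.0 × 0.5 m footprint, 0.4 m tall),
depth noise 0.01 m, dropout 2%. Randomized recovery experiments draw
`a ∈ [0.40, 0.55]`, `b ∈ [0.20, 0.30]`, `c ∈ [0.30, 0.45]` m and a
uniform pose — plausible grower-pig dimensions. Problem sizes (20 noisy
phantoms, 50 random convex blobs, 100 random detection sets, 10
evaluation scenes) keep the full suite and the acceptance script under a
minute while leaving the stochastic margins clearly resolved.

What the phantoms do **not** emulate: articulated limbs and head/tail
asymmetry, non-convex postures, contacting or occluding animals,
perspective distortion (the camera is treated as orthographic),
correlated sensor noise, and edge-dependent dropout. Passing recovery
tests therefore demonstrates the correctness of the measurement
pipeline, not field accuracy on real animals.

## Error budget observed under the default conditions

Noise-free, truth mask, no smoothing: all features within 0.5% of closed
form (apex height exact). Full noisy pipeline (classical segmentation at
0.05 m, fill, `sigma = 1`): worst single-feature error across 20 seeded
phantoms ≈ 4–6%, dominated by the threshold-rim bias on mean height and
the dropout sensitivity of the centroid height described above.

## Known limitations

* Measurements assume one connected, convex-ish body per mask; the 3D
  path reduces multi-instance masks to the highest-score instance.
* The min-rect angle is a coarse pose estimate on smooth elongated
  bodies (see above).
* Mean filling is global; a local (neighborhood) fill would be less
  biased for large holes but is deliberately not used — the pipeline
  follows the simple global rule so results remain easy to reason about
  and reproduce.
* `height_centroid` inherits single-pixel noise; prefer
  `height_average` for downstream modeling when both are available.
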