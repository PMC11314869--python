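# Methods

## Measurement model

A depth camera looks straight down at a tank. For each frame it reports a
grid of z-depths (range along the optical axis, millimetres, 0 = no
measurement). A segmentation mask marks the fish. The quantity of interest
is the fish's body volume, converted to mass by a density coefficient.

Assumptions, in decreasing order of importance:

1. **The fish rests on (or near) the bottom.** Thickness is measured
   against the *bottom* depth, not the fish's own underside, which the
   camera cannot see. A fish hovering `h` mm above the bottom inflates the
   volume by approximately `h x (plan area)`; the synthetic generator can
   reproduce this deliberately via its `clearance` parameter, and the test
   suite asserts the predicted inflation.
2. **The bottom is locally planar around the fish.** The ring estimator
   averages background depths in a disk-dilated band around the mask
   (default width 5 px — wide enough to average sensor noise, narrow
   enough that local planarity holds). A symmetric ring cancels any planar
   tilt exactly, so the estimate is unbiased at the fish's position; on a
   strongly curved (bowl) bottom a residual bias of order the sagitta
   across the ring remains.
3. **Nadir view, one fish per frame.** Multi-instance frames are handled
   by processing each mask independently; occlusion between fish is out of
   scope.
4. **Refraction is ignored.** Both the bottom and the fish surface are
   viewed through the same air-water interface; to first order the
   *difference* of their apparent depths rescales by the refractive index,
   which the density calibration absorbs as a multiplicative factor.

## Volume integration

Per mask pixel with valid depth, thickness `t(p) = z_b - z(p)`, clamped at
0 (negative values arise from noise; the clamped count is reported for
QC).

**Metric mode (default).** A pixel's viewing cone has cross-section
`z^2/(fx fy)` at range z. Integrating that cross-section between the
surface and the bottom gives the exact volume of the pixel's cone-frustum:

    V = sum_p (z_b^3 - z(p)^3) / (3 fx fy)
      = sum_p t(p) (z^2 + z z_b + z_b^2) / (3 fx fy)

The union of these frusta over the mask tiles the solid between the
surface and the bottom plane exactly (up to pixel discretization and a
negligible silhouette sliver), so no distance correction is needed: on
noise-free phantoms the measured error is below 0.05% for fish half-lengths
80-250 mm at 0.8-1.2 m. The simpler surface-footprint choice
`t(p) z(p)^2/(fx fy)` was evaluated and rejected: it ignores the widening
of the cone between surface and bottom and biases the volume low by 1-4%,
the more the thicker the fish and the closer the camera.

**Paper mode.** Thickness is first summed in pixel units,
`V_px = sum t(p)` (mm px), then corrected for the camera-to-fish distance
`y` by similar triangles, `V_corrected = V_px (y/y_ref)^2`, and converted
to mm^3 with the constant footprint at the reference distance `y_ref`.
This mirrors calibrating at one height and correcting all other heights to
it, and is exposed as `--mode paper --y-ref <mm>`. The scalar `y` is the
mean *mid-column* depth `(surface + bottom)/2`, i.e. the distance to the
fish's volume centroid: using the surface depth instead under-scales thick
fish by roughly the thickness-to-range ratio (up to ~4% for the largest
phantoms), while the mid-column choice keeps the two modes within 0.4% of
each other everywhere tested.

`correct_volume` is duck-typed; with `fractions.Fraction` inputs the
similar-triangles rescale is exact and composes to the identity.

## Mass model

`m = rho V`, least squares through the origin (`rho = sum mV / sum V^2`)
when (volume, mass) calibration pairs are available — zero volume must map
to zero mass, which an affine fit would not guarantee — otherwise the
default `rho = 1.05 g/cm^3`, near-neutral buoyancy of teleost tissue,
always logged. How best to map reconstructed volume to mass is genuinely
open (condition factor varies seasonally and by species); the
through-origin regression is the minimal defensible model and its fit R^2
is reported so a poor linear fit is visible.

Per-fish aggregation over n frames: mean, sample SD (ddof = 1), and a
Student-t 95% CI (`mean +/- t_{0.975, n-1} SD / sqrt(n)`); t rather than
normal so small test groups are covered.

## Camera model

Pinhole, no lens distortion (no distortion coefficients are available for
the shipped rig). Pixels are (u, v) = (column, row), 0-based, centers at
integers. The depth camera frame is the world frame unless a calibration
file overrides it. Registration resamples by nearest-integer landing with
a nearest-surface-wins collision rule (occlusion-correct); no splatting or
interpolation, keeping the operation deterministic. Calibration rotation
matrices printed at 3-decimal precision are not exactly orthonormal; on
load they are projected to the nearest rotation (orthogonal Procrustes,
SVD) with a warning, and matrices more than 5% from orthonormal are
rejected as malformed.

## Synthetic scenes

The generator emulates the study conditions the pipeline is meant for:

| parameter | default | rationale |
|---|---|---|
| camera height | uniform 0.8-1.2 m | working range of an overhead rig above a shallow tank |
| fish shape | half-ellipsoid, flat base down | matches the thickness-from-above model; closed-form volume (2/3) pi a b c |
| half-length a | uniform 80-250 mm | juvenile-to-adult sturgeon-sized bodies |
| half-width b | a x U(0.22, 0.28) | elongated fusiform plan view |
| height c | a x U(0.15, 0.20) | dorsoventral profile of a resting fish |
| bottom | plane, tilt up to +/-0.02 | gently non-flat tank floor exercising the ring estimator |
| noise sigma(z) | 0.02 z^2 / 4000 mm | stereo range error grows with z^2; equals 2% of range at 4 m, the published figure for this sensor class |
| dropout | 1% of pixels | holes in real depth maps |
| density | 1.05 g/cm^3 | same tissue-density convention as the mass model |
| detection set | 27 fish x 60 frames at 640x360 | one experimental group; the moderate resolution keeps a full run to a couple of minutes while leaving >1000 px on the smallest fish |

Rendering is per-pixel ray casting against the analytic surfaces (no mesh,
no rasterization library), so the recorded depth is exact to float
precision; the quadratic for each half-ellipsoid is solved only inside its
projected bounding window for speed. Depth PNGs are 16-bit and quantize to
whole millimetres, as real sensors report.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: water-surface ripple and specular reflections
(the dominant error source in practice), refraction, fish body curvature
and fin detail beyond an ellipsoid, motion blur, and segmentation errors
(truth masks are geometrically perfect; the depth-threshold segmenter is a
stand-in, not a model of a learned segmenter's failure modes).

## Numerical choices and QC

- Negative thickness clamps to 0 rather than erroring; with sigma ~5 mm at
  1 m the induced positive bias scales as 0.4 (sigma/c)^3 and is <0.1% for
  realistic bodies.
- Frames are rejected, with a reason code in a JSON-lines QC log, when:
  the mask is empty after cleaning (`empty-mask`); the mask leaves no
  background ring (`ring-empty`); fewer than 10 valid ring pixels remain
  (`ring-invalid`); or more than 50% of mask pixels lack depth
  (`invalid-depth-excess`). A fish with fewer than two surviving frames is
  flagged in the per-fish table, never dropped.
- Mask cleanup keeps the largest 8-connected component and fills interior
  holes; the ring uses a disk structuring element so the band is
  direction-isotropic.
- The ring average is the mean ("averaging" taken literally); a median
  option exists for bottoms with outlier pixels.
- All distances are mm and volumes mm^3 internally; g/cm^3 appears only at
  the density interface.
- Determinism: every stochastic component takes a seed or Generator;
  pipeline CSVs are written with a fixed float format so identical
  configurations are byte-identical.

## Problem sizes

Unit tests run on 64x64 to 1280x720 single frames. The end-to-end
recovery check and the acceptance script use the full 27 fish x 60 frames
detection set at 640x360 with default noise (~1600 rendered frames, a few
minutes on one CPU); accuracy and invariance checks use noise-free
1280x720 frames where discretization is the only error source.

## Known limitations

- Accuracy degrades off-nadir; the silhouette sliver argument above
  assumes near-vertical rays.
- The bottom estimator reads the ring, so debris or a second fish inside
  the ring biases the bottom depth; the median option mitigates point
  outliers only.
- The density coefficient conflates tissue density, refraction scaling,
  and any systematic segmentation bias; it should be calibrated per
  deployment rather than trusted at 1.05.
- Bowl-shaped bottoms are supported by the renderer but the estimator
  still assumes local planarity under the fish.
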