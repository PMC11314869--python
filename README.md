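# fishvol

Non-contact volume and mass estimation of farmed fish from a single
overhead RGB-D camera.

Weighing fish by netting them out of the tank is slow and stressful for
the animals. `fishvol` implements the alternative: a depth camera mounted
above the water sees both the tank bottom and the fish's upper surface, so
the fish's body volume can be reconstructed directly from one depth frame
and a segmentation mask — no handling, no stereo rig of your own, no
species-specific shape model.

## Method

For a fish resting on the bottom, seen at nadir:

1. **Registration.** Depth frames are registered into the color camera's
   pixel grid (where segmentation masks live) by the standard pinhole
   chain: deproject each depth pixel with `K_depth`, apply the rig
   extrinsics `(R, T)`, reproject with `K_rgb`. A calibrated Intel
   RealSense D455 parameter set ships with the package.
2. **Bottom depth.** The bottom under the fish is occluded, so its depth
   `z_b` is estimated by averaging the valid depths in a perimeter ring —
   a disk-dilated band of background pixels hugging the mask. On a locally
   planar bottom a symmetric ring makes the mean unbiased at the fish's
   position.
3. **Thickness integral.** Per mask pixel, thickness `t(p) = z_b − z(p)`.
   The volume is the thickness integrated over the physical area each
   pixel subtends. A pixel's viewing cone has cross-section
   `z² / (fx·fy)` at range `z`, so the exact per-pixel contribution is the
   cone-frustum volume between the surface and the bottom:

   V = Σ_p (z_b³ − z(p)³) / (3·fx·fy) = Σ_p t(p)·(z² + z·z_b + z_b²) / (3·fx·fy)

   Because the footprint carries its own range dependence, the estimate is
   invariant to the camera-to-fish distance by construction. A `paper`
   mode is also provided that sums thickness in pixel units and applies
   the similar-triangles correction `V_corrected = V·(y₂/y₁)²` against a
   calibrated reference distance.
4. **Mass.** `m = ρ·V` with the tissue density `ρ` either calibrated from
   (volume, mass) pairs by least squares through the origin or defaulted
   to 1.05 g/cm³ (near-neutral buoyancy). Per-fish estimates aggregate
   many frames: mean, SD, and a Student-t 95% CI.

Every stage is validated on synthetic scenes rendered by per-pixel ray
casting: half-ellipsoid fish phantoms with closed-form volume
`(2/3)·π·a·b·c` over flat, tilted, or bowl-shaped bottoms, with stereo
range noise growing as `z²` (2% of range at 4 m) and pixel dropout.

## Worked example

```python
from fishvol import (FishPhantom, PlanarBottom, SceneConfig, render_scene,
                     FishMask, estimate_frame_volume, load_default_calibration,
                     DensityModel, volume_to_mass)

rig = load_default_calibration()
fish = FishPhantom(semi_axes=(150.0, 40.0, 30.0), center=(30.0, -20.0),
                   heading=0.6, rest_depth=1000.0)
cfg = SceneConfig(camera_height=1000.0, bottom=PlanarBottom(1000.0),
                  phantoms=[fish], resolution=(1280, 720))
frame, masks, truth = render_scene(cfg, rig)

est = estimate_frame_volume(frame, FishMask(masks[0]), rig.depth)
mass = volume_to_mass(est.volume_mm3, DensityModel(rho_g_cm3=1.05))
```

prints, via the obvious formatting:

```
true volume   :   376991.1 mm^3
estimated     :   377006.3 mm^3 (+0.00%)
bottom depth  :   1000.0 mm
surface depth :    979.6 mm (mean)
mask pixels   : 7951
mass at 1.05 g/cm^3: 395.9 g
```

A 30 cm phantom at 1 m gives back its analytic volume to within a few
hundredths of a percent; with realistic sensor noise, per-fish means over
60 frames stay within a few percent.

The same flow from the shell:

```sh
fishvol simulate --n-fish 27 --frames 60 --seed 42 --out scene/
fishvol estimate --depth scene/depth --mask scene/mask --out results/
fishvol eval --pred results/per_fish.csv --truth scene/truth.csv
fishvol calibrate-density --pairs pairs.csv   # (volume_mm3, mass_g) CSV
```

`fishvol estimate` writes `per_frame.csv`, `per_fish.csv` (mean mass, SD,
95% CI per individual) and a JSON-lines QC log in which every rejected
frame appears with a reason code — no frame is silently dropped.

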