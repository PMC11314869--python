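"""Bottom-depth estimation, thickness maps, and volume integration.

The measurement principle: seen from straight above, a fish resting on the
tank bottom occludes the bottom, and its per-pixel *thickness* is the
difference between the bottom depth and the depth of its upper surface.
The bottom depth under the fish is unobservable, so it is estimated from a
perimeter ring of background pixels around the mask.  Summing thickness
times the physical area each pixel subtends yields the body volume.

Two integration modes are provided:

``metric`` (default)
    Each mask pixel contributes the exact volume of its viewing-cone
    frustum between the measured surface depth ``z`` and the bottom depth
    ``z_b``: ``(z_b^3 - z^3) / (3 fx fy) = t * (z^2 + z z_b + z_b^2) /
    (3 fx fy)``.  Because the pixel footprint carries its own ``z^2``
    range dependence, the result is a physical volume that is invariant to
    the camera-to-fish distance by construction.

``paper``
    Thickness is summed in pixel units (mm * px) at the fish's distance
    ``y`` and rescaled to a reference distance ``y_ref`` by the
    similar-triangles correction ``V_corrected = V * (y / y_ref)^2``,
    then converted to mm^3 with the constant footprint at ``y_ref``.  This
    mirrors measuring at one calibrated height and correcting other
    heights to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .camera_model import Intrinsics
from .errors import QCRejection
from .frames import DepthFrame
from .segmentation_io import FishMask

__all__ = [
    "ThicknessMap",
    "VolumeEstimate",
    "estimate_bottom_depth",
    "thickness_map",
    "integrate_volume_metric",
    "integrate_volume_paper",
    "correct_volume",
    "fish_distance",
    "estimate_frame_volume",
]

#: minimum number of valid ring pixels for a usable bottom estimate
MIN_RING_PIXELS = 10
#: reject frames where more than this fraction of mask pixels lack depth
MAX_INVALID_FRACTION = 0.5


@dataclass
class ThicknessMap:
    """Per-pixel fish thickness in mm (0 outside the mask)."""

    grid: np.ndarray
    bottom_depth: float
    mean_surface_depth: float
    valid: np.ndarray  # mask pixels with a usable depth
    n_pixels: int
    n_clamped: int
    n_invalid: int


@dataclass
class VolumeEstimate:
    """A physical volume plus the intermediates that produced it."""

    volume_mm3: float
    mode: str
    bottom_depth: float
    mean_surface_depth: float
    n_pixels: int
    n_clamped: int
    reference_depth: float | None = None

    def __post_init__(self):
        if self.volume_mm3 < 0:
            raise ValueError("volume cannot be negative")
        if self.n_clamped > self.n_pixels:
            raise ValueError("clamped count exceeds pixel count")


def estimate_bottom_depth(frame: DepthFrame, ring: np.ndarray,
                          method: str = "mean",
                          min_valid: int = MIN_RING_PIXELS) -> float:
    """Estimate the bottom depth under the fish from its perimeter ring.

    Averages (or takes the median of) the valid depths in the ring.  On a
    locally planar bottom a ring symmetric around the fish averages out any
    tilt, so the mean is unbiased at the fish's location.
    """
    vals = frame.data[np.asarray(ring, dtype=bool)]
    vals = vals[vals > 0]
    if vals.size < min_valid:
        raise QCRejection("ring-invalid",
                          f"only {vals.size} valid ring pixels (< {min_valid})")
    if method == "mean":
        return float(vals.mean())
    if method == "median":
        return float(np.median(vals))
    raise ValueError(f"unknown method {method!r}")


def thickness_map(frame: DepthFrame, mask: FishMask, bottom: float) -> ThicknessMap:
    """Per-pixel thickness t = bottom - z over the mask.

    Negative thickness (surface measured below the estimated bottom, a
    noise artifact) is clamped to 0 and counted; mask pixels with invalid
    depth are excluded and counted.  Frames where more than half the mask
    lacks depth are rejected.
    """
    if not bottom > 0:
        raise ValueError(f"bottom depth must be positive, got {bottom}")
    m = mask.grid
    valid = m & frame.valid
    n_mask = int(m.sum())
    n_invalid = n_mask - int(valid.sum())
    if n_mask == 0 or n_invalid > MAX_INVALID_FRACTION * n_mask:
        raise QCRejection("invalid-depth-excess",
                          f"{n_invalid}/{n_mask} mask pixels lack depth")
    z = frame.data[valid]
    t = bottom - z
    n_clamped = int((t < 0).sum())
    grid = np.zeros(frame.shape)
    grid[valid] = np.maximum(t, 0.0)
    return ThicknessMap(
        grid=grid,
        bottom_depth=float(bottom),
        mean_surface_depth=float(z.mean()),
        valid=valid,
        n_pixels=int(valid.sum()),
        n_clamped=n_clamped,
        n_invalid=n_invalid,
    )


def integrate_volume_metric(t: ThicknessMap, frame: DepthFrame, K: Intrinsics
                            ) -> VolumeEstimate:
    """Sum per-pixel frustum volumes into a physical volume (mm^3).

    Each pixel's viewing cone has cross-section ``z^2 / (fx fy)`` at range
    z; integrating that between the surface depth and the bottom depth
    gives the exact cone-slab volume ``t * (z^2 + z z_b + z_b^2) /
    (3 fx fy)``, which is what a pixel of the fish actually occupies.
    Linear in the thickness grid.
    """
    if t.n_pixels == 0:
        raise ValueError("empty thickness map")
    z = frame.data[t.valid]
    zb = t.bottom_depth
    footprint = (z**2 + z * zb + zb**2) / (3.0 * K.fx * K.fy)
    volume = float(np.sum(t.grid[t.valid] * footprint))
    return VolumeEstimate(
        volume_mm3=volume,
        mode="metric",
        bottom_depth=t.bottom_depth,
        mean_surface_depth=t.mean_surface_depth,
        n_pixels=t.n_pixels,
        n_clamped=t.n_clamped,
    )


def integrate_volume_paper(t: ThicknessMap, y: float, y_ref: float, K: Intrinsics
                           ) -> VolumeEstimate:
    """Pixel-domain integration with the similar-triangles distance correction.

    The raw pixel-domain sum ``V_px = sum(t)`` (mm * px) taken at fish
    distance ``y`` is rescaled to the reference distance by
    ``(y / y_ref)^2`` and converted to mm^3 with the constant pixel
    footprint ``y_ref^2 / (fx fy)`` — equivalently ``V_px * y^2 /
    (fx fy)``.
    """
    if y_ref is None:
        raise ValueError("paper mode requires a reference distance y_ref")
    if not (y > 0 and y_ref > 0):
        raise ValueError("distances must be positive")
    if t.n_pixels == 0:
        raise ValueError("empty thickness map")
    v_px = float(np.sum(t.grid[t.valid]))
    volume = correct_volume(v_px, y_ref, y) * y_ref**2 / (K.fx * K.fy)
    return VolumeEstimate(
        volume_mm3=float(volume),
        mode="paper",
        bottom_depth=t.bottom_depth,
        mean_surface_depth=t.mean_surface_depth,
        n_pixels=t.n_pixels,
        n_clamped=t.n_clamped,
        reference_depth=float(y_ref),
    )


def correct_volume(V, y_ref, y):
    """Similar-triangles distance correction: ``V * (y / y_ref)^2``.

    Rescales a volume measured with the camera at distance ``y`` to the
    scale of a measurement taken at ``y_ref``.  Duck-typed: with
    :class:`fractions.Fraction` inputs the result is exact;
    ``correct_volume(correct_volume(V, a, b), b, a)`` then returns ``V``
    identically.
    """
    if not (y > 0 and y_ref > 0):
        raise ValueError("distances must be positive")
    return V * (y * y) / (y_ref * y_ref)


def fish_distance(t: ThicknessMap) -> float:
    """Scalar camera-to-fish distance: the mean mid-column depth.

    The fish occupies depths between its upper surface and the bottom; its
    volume centroid sits near the middle of that column, so the mid-column
    mean is the representative distance for the similar-triangles
    correction (using the surface depth instead biases thick fish by
    roughly the thickness-to-range ratio).
    """
    return 0.5 * (t.mean_surface_depth + t.bottom_depth)


def estimate_frame_volume(frame: DepthFrame, mask: FishMask, K: Intrinsics,
                          ring_width: int = 5, mode: str = "metric",
                          y_ref: float | None = None,
                          bottom_method: str = "mean") -> VolumeEstimate:
    """Convenience: ring -> bottom -> thickness -> volume for one frame.

    The mask-validity gate runs first so that a frame with (mostly) missing
    depth is rejected as ``invalid-depth-excess`` rather than as a ring
    failure.
    """
    from .segmentation_io import extract_ring

    n_mask = int(mask.grid.sum())
    n_valid = int((mask.grid & frame.valid).sum())
    if n_mask == 0 or n_mask - n_valid > MAX_INVALID_FRACTION * n_mask:
        raise QCRejection("invalid-depth-excess",
                          f"{n_mask - n_valid}/{n_mask} mask pixels lack depth")
    ring = extract_ring(mask, ring_width)
    bottom = estimate_bottom_depth(frame, ring, method=bottom_method)
    t = thickness_map(frame, mask, bottom)
    if mode == "metric":
        return integrate_volume_metric(t, frame, K)
    if mode == "paper":
        if y_ref is None:
            raise ValueError("mode='paper' requires y_ref")
        return integrate_volume_paper(t, fish_distance(t), y_ref, K)
    raise ValueError(f"unknown mode {mode!r}")
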