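"""Mask ingestion, cleanup, and perimeter-ring extraction.

The volume pipeline consumes one binary mask per fish per frame.  Masks may
come from any instance segmenter; supported on-disk formats are 8-bit PNG
(nonzero = fish), Labelme-dialect polygon JSON, and YOLO-seg text lines
(class id followed by normalized polygon vertices).  A trivial
depth-threshold segmenter is provided for synthetic scenes where the bottom
depth is known.

The perimeter ring — a band of background pixels hugging the fish outline —
is what the bottom-depth estimator averages over; it is built by disk
dilation so the band is direction-isotropic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.draw import polygon2mask
from skimage.measure import label as cc_label
from skimage.morphology import disk

from .errors import EmptyMaskError, MaskFormatError, RingEmptyError
from .frames import DepthFrame

__all__ = [
    "FishMask",
    "read_mask",
    "clean_mask",
    "extract_ring",
    "threshold_segment",
]

#: default minimum component area in pixels accepted by clean_mask
DEFAULT_MIN_AREA = 32


@dataclass
class FishMask:
    """Binary pixel grid marking one fish instance."""

    grid: np.ndarray
    label: str | None = None
    confidence: float | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise MaskFormatError("mask must be a 2D grid")

    @property
    def area(self) -> int:
        return int(self.grid.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


def _fill_polygons(polys: list[np.ndarray], shape: tuple[int, int]) -> np.ndarray:
    grid = np.zeros(shape, dtype=bool)
    for poly in polys:
        if poly.shape[0] < 3:
            raise MaskFormatError(f"polygon needs >= 3 vertices, got {poly.shape[0]}")
        # polygon2mask wants (row, col); annotation points are (x, y)
        grid |= polygon2mask(shape, poly[:, ::-1])
    return grid


def read_mask(path: str | Path, shape: tuple[int, int] | None = None) -> FishMask:
    """Read a fish mask, auto-detecting the format from the extension.

    ``shape`` (rows, cols) is required for polygon formats unless the file
    itself records the image size (Labelme does); it is checked against
    raster masks when given.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".png":
        arr = iio.imread(path)
        if arr.ndim == 3:
            arr = arr[..., 0]
        grid = arr > 0
        if shape is not None and grid.shape != tuple(shape):
            raise MaskFormatError(f"{path}: mask shape {grid.shape} != expected {tuple(shape)}")
        label = None
    elif suffix == ".json":
        with open(path) as fh:
            doc = json.load(fh)
        if "shapes" not in doc:
            raise MaskFormatError(f"{path}: not a Labelme annotation (no 'shapes')")
        if shape is None:
            try:
                shape = (int(doc["imageHeight"]), int(doc["imageWidth"]))
            except KeyError:
                raise MaskFormatError(f"{path}: image size absent; pass shape=") from None
        polys = [np.asarray(s["points"], dtype=float) for s in doc["shapes"]]
        if not polys:
            raise MaskFormatError(f"{path}: no shapes")
        grid = _fill_polygons(polys, tuple(shape))
        label = doc["shapes"][0].get("label")
    elif suffix == ".txt":
        if shape is None:
            raise MaskFormatError(f"{path}: YOLO-seg masks need an explicit shape=")
        H, W = shape
        polys, label = [], None
        for line in path.read_text().splitlines():
            parts = line.split()
            if not parts:
                continue
            if label is None:
                label = parts[0]
            coords = np.asarray(parts[1:], dtype=float)
            if coords.size % 2:
                raise MaskFormatError(f"{path}: odd number of polygon coordinates")
            poly = coords.reshape(-1, 2) * [W, H]
            polys.append(poly)
        if not polys:
            raise MaskFormatError(f"{path}: empty annotation file")
        grid = _fill_polygons(polys, (H, W))
    else:
        raise MaskFormatError(f"{path}: unknown mask format '{suffix}'")
    if not grid.any():
        raise EmptyMaskError(f"{path}: no foreground pixels")
    return FishMask(grid, label=label)


def clean_mask(mask: FishMask, min_area: int = DEFAULT_MIN_AREA) -> FishMask:
    """Keep the largest 8-connected component and fill interior holes.

    Raises :class:`EmptyMaskError` if the surviving component is smaller
    than ``min_area`` pixels.  Idempotent.
    """
    labels, n = cc_label(mask.grid, connectivity=2, return_num=True)
    if n == 0:
        raise EmptyMaskError("mask has no foreground pixels")
    areas = np.bincount(labels.ravel())[1:]
    keep = int(np.argmax(areas)) + 1
    grid = ndimage.binary_fill_holes(labels == keep)
    if grid.sum() < min_area:
        raise EmptyMaskError(
            f"largest component has {int(grid.sum())} px < min_area={min_area}"
        )
    return FishMask(grid, label=mask.label, confidence=mask.confidence)


def extract_ring(mask: FishMask | np.ndarray, width: int = 5) -> np.ndarray:
    """Band of background pixels surrounding the mask, by disk dilation.

    ``ring = dilate(mask, disk(width)) & ~mask``, clipped to the frame.
    Always disjoint from the mask.  Raises :class:`RingEmptyError` when the
    mask covers the frame so completely that no ring pixel remains.
    """
    if width < 1:
        raise ValueError(f"ring width must be >= 1, got {width}")
    grid = mask.grid if isinstance(mask, FishMask) else np.asarray(mask, dtype=bool)
    ring = ndimage.binary_dilation(grid, structure=disk(width)) & ~grid
    if not ring.any():
        raise RingEmptyError("no background pixels available around the mask")
    return ring


def threshold_segment(frame: DepthFrame, bottom_z_hint: float, margin: float = 5.0,
                      min_area: int = DEFAULT_MIN_AREA) -> FishMask:
    """Segment anything standing proud of the bottom by a depth threshold.

    Pixels with ``0 < z < bottom_z_hint - margin`` are foreground; the
    result is cleaned with :func:`clean_mask`.  A stand-in segmenter for
    synthetic scenes (real deployments use a learned instance segmenter).
    """
    if margin <= 0:
        raise ValueError(f"margin must be positive, got {margin}")
    grid = (frame.data > 0) & (frame.data < bottom_z_hint - margin)
    if not grid.any():
        raise EmptyMaskError("no pixels rise above the bottom by more than margin")
    return clean_mask(FishMask(grid), min_area=min_area)
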