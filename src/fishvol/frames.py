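"""Depth-frame container and 16-bit PNG I/O.

Depth frames follow the RealSense convention: a single-channel image whose
pixel values are ranges in millimetres along the optical axis (z-depth),
with 0 encoding "no measurement".  On disk they are 16-bit PNGs; in memory
the grid is float64 so that noise models and sub-millimetre synthetic
scenes are not quantized until written out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["DepthFrame", "read_depth_png", "write_depth_png"]


@dataclass
class DepthFrame:
    """A 2D grid of z-depths in mm; 0 marks invalid pixels."""

    data: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("depth frame must be a 2D array")
        if np.any(self.data < 0):
            raise ValueError("depth values must be non-negative (0 = invalid)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean grid of pixels carrying a measurement."""
        return self.data > 0

    def copy(self) -> "DepthFrame":
        return DepthFrame(self.data.copy(), dict(self.meta))


def read_depth_png(path: str | Path, meta: dict | None = None) -> DepthFrame:
    """Read a 16-bit single-channel PNG of millimetre depths."""
    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: depth PNG must be single-channel")
    return DepthFrame(arr.astype(np.float64), meta or {"path": str(path)})


def write_depth_png(frame: DepthFrame, path: str | Path) -> None:
    """Write a depth frame as 16-bit PNG, rounding to whole millimetres."""
    out = np.clip(np.rint(frame.data), 0, np.iinfo(np.uint16).max)
    iio.imwrite(Path(path), out.astype(np.uint16))
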