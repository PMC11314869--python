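"""Pinhole camera geometry and depth-to-color registration.

An overhead RGB-D rig pairs a depth (stereo IR) camera with a color camera a
few centimetres away.  Volume integration works in the depth camera's pixel
grid, but masks produced from the color stream live in the color camera's
grid, so depth frames must be re-registered: every valid depth pixel is
deprojected to a 3D point with the depth intrinsics, moved into the color
camera frame by the rig extrinsics, and reprojected with the color
intrinsics.

Conventions
-----------
* Pixels are (u, v) = (column, row), 0-based, with pixel centers at integer
  coordinates.  Principal points from calibration are interpreted the same
  way.
* All distances are millimetres; depth 0 is invalid.
* The depth camera frame doubles as the world frame unless a calibration
  file supplies an explicit depth-to-world transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import BehindCameraError, CalibrationError, InvalidDepthError
from .frames import DepthFrame

__all__ = [
    "Intrinsics",
    "Extrinsics",
    "CameraRig",
    "Point3D",
    "deproject",
    "project",
    "transform",
    "align_depth_to_color",
    "load_calibration",
    "default_calibration_path",
    "load_default_calibration",
]

FRAME_DEPTH = "depth-camera"
FRAME_COLOR = "color-camera"
FRAME_WORLD = "world"

_ORTHO_TOL = 1e-6  # invariant tolerance after load
_ORTHO_REJECT = 0.05  # beyond this the matrix is junk, not rounding


@dataclass(frozen=True)
class Intrinsics:
    """Pinhole intrinsics: focal lengths and principal point, in pixels."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int | None = None
    height: int | None = None

    def __post_init__(self):
        if not (self.fx > 0 and self.fy > 0):
            raise CalibrationError(f"focal lengths must be positive, got fx={self.fx}, fy={self.fy}")
        if not (np.isfinite(self.cx) and np.isfinite(self.cy)):
            raise CalibrationError("principal point must be finite")

    def scaled(self, factor: float) -> "Intrinsics":
        """Intrinsics for the same camera at a resized resolution."""
        return Intrinsics(
            self.fx * factor,
            self.fy * factor,
            self.cx * factor,
            self.cy * factor,
            None if self.width is None else int(round(self.width * factor)),
            None if self.height is None else int(round(self.height * factor)),
        )


def _nearest_rotation(M: np.ndarray) -> np.ndarray:
    """Project a near-rotation onto SO(3) (orthogonal Procrustes)."""
    U, _, Vt = np.linalg.svd(M)
    R = U @ Vt
    if np.linalg.det(R) < 0:  # reflection: flip the smallest singular direction
        U[:, -1] *= -1
        R = U @ Vt
    return R


@dataclass(frozen=True)
class Extrinsics:
    """Rigid transform between camera frames: p' = R p + T (T in mm)."""

    R: np.ndarray
    T: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "R", np.asarray(self.R, dtype=np.float64).reshape(3, 3))
        object.__setattr__(self, "T", np.asarray(self.T, dtype=np.float64).reshape(3))
        err = np.abs(self.R.T @ self.R - np.eye(3)).max()
        if err > _ORTHO_TOL or abs(np.linalg.det(self.R) - 1.0) > _ORTHO_TOL:
            raise CalibrationError(
                f"rotation not orthonormal (max deviation {err:.2e}); "
                "use Extrinsics.from_values to orthonormalize calibration output"
            )

    @classmethod
    def from_values(cls, R, T) -> "Extrinsics":
        """Build from raw calibration numbers, snapping R to the nearest rotation.

        Printed calibration matrices are typically rounded to 3 decimals and
        are not exactly orthonormal; deviations up to ~5% are repaired with a
        warning, anything larger is rejected as malformed.
        """
        R = np.asarray(R, dtype=np.float64).reshape(3, 3)
        err = np.abs(R.T @ R - np.eye(3)).max()
        if err > _ORTHO_REJECT:
            raise CalibrationError(f"rotation far from orthonormal (deviation {err:.3f})")
        if err > _ORTHO_TOL:
            warnings.warn(
                f"rotation deviates from orthonormality by {err:.2e}; "
                "projecting to the nearest rotation",
                stacklevel=2,
            )
            R = _nearest_rotation(R)
        return cls(R, np.asarray(T, dtype=np.float64).reshape(3))

    @classmethod
    def identity(cls) -> "Extrinsics":
        return cls(np.eye(3), np.zeros(3))

    def inverse(self) -> "Extrinsics":
        return Extrinsics(self.R.T, -self.R.T @ self.T)


@dataclass(frozen=True)
class CameraRig:
    """Calibrated overhead rig: depth + color intrinsics and their extrinsics."""

    depth: Intrinsics
    color: Intrinsics
    depth_to_color: Extrinsics
    depth_to_world: Extrinsics = field(default_factory=Extrinsics.identity)
    right_to_left: Extrinsics | None = None  # stereo IR baseline pair, informational


@dataclass(frozen=True)
class Point3D:
    """A 3D point in mm, tagged with the camera frame it lives in."""

    x: float
    y: float
    z: float
    frame: str = FRAME_DEPTH

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=np.float64)


def deproject(pixel: tuple[float, float], depth: float, K: Intrinsics,
              frame: str = FRAME_DEPTH) -> Point3D:
    """Back-project a pixel with known range to a 3D camera-frame point.

    x = (u - cx) * depth / fx, y = (v - cy) * depth / fy, z = depth.
    """
    if not depth > 0:
        raise InvalidDepthError(f"depth must be positive, got {depth}")
    u, v = pixel
    return Point3D(
        (u - K.cx) * depth / K.fx,
        (v - K.cy) * depth / K.fy,
        float(depth),
        frame,
    )


def project(p: Point3D, K: Intrinsics) -> tuple[float, float]:
    """Project a camera-frame point onto the pixel plane (u, v)."""
    if not p.z > 0:
        raise BehindCameraError(f"cannot project point with z={p.z}")
    return (K.fx * p.x / p.z + K.cx, K.fy * p.y / p.z + K.cy)


def transform(p: Point3D, E: Extrinsics, frame: str | None = None) -> Point3D:
    """Apply a rigid transform: p' = R p + T."""
    q = E.R @ p.as_array() + E.T
    return Point3D(float(q[0]), float(q[1]), float(q[2]), frame or p.frame)


def align_depth_to_color(frame: DepthFrame, rig: CameraRig) -> DepthFrame:
    """Resample a depth frame into the color camera's pixel grid.

    Each valid depth pixel is deprojected with the depth intrinsics,
    transformed by the depth-to-color extrinsics, and projected with the
    color intrinsics; its new z is written at the nearest-integer landing
    pixel.  When two source pixels land on the same output pixel the smaller
    z wins (the nearer surface occludes).  Output pixels that receive no
    landing stay 0/invalid; landings outside the color grid are dropped.
    """
    Kd, Kc, E = rig.depth, rig.color, rig.depth_to_color
    if Kd.width is not None and frame.shape != (Kd.height, Kd.width):
        raise ValueError(
            f"frame shape {frame.shape} does not match depth intrinsics "
            f"({Kd.height}, {Kd.width})"
        )
    out_h = Kc.height if Kc.height is not None else frame.shape[0]
    out_w = Kc.width if Kc.width is not None else frame.shape[1]

    vs, us = np.nonzero(frame.valid)
    z = frame.data[vs, us]
    pts = np.empty((3, z.size))
    pts[0] = (us - Kd.cx) * z / Kd.fx
    pts[1] = (vs - Kd.cy) * z / Kd.fy
    pts[2] = z
    pts = E.R @ pts + E.T[:, None]
    z2 = pts[2]
    ok = z2 > 0
    u2 = np.rint(Kc.fx * pts[0, ok] / z2[ok] + Kc.cx).astype(np.int64)
    v2 = np.rint(Kc.fy * pts[1, ok] / z2[ok] + Kc.cy).astype(np.int64)
    z2 = z2[ok]
    inb = (u2 >= 0) & (u2 < out_w) & (v2 >= 0) & (v2 < out_h)

    out = np.full((out_h, out_w), np.inf)
    np.minimum.at(out, (v2[inb], u2[inb]), z2[inb])
    out[~np.isfinite(out)] = 0.0
    return DepthFrame(out, {**frame.meta, "geometry": "color"})


def _read_intrinsics(d: dict, name: str) -> Intrinsics:
    try:
        return Intrinsics(
            float(d["fx"]), float(d["fy"]), float(d["cx"]), float(d["cy"]),
            int(d["width"]) if "width" in d else None,
            int(d["height"]) if "height" in d else None,
        )
    except KeyError as e:
        raise CalibrationError(f"calibration section '{name}' missing field {e}") from e


def _read_extrinsics(d: dict, name: str) -> Extrinsics:
    try:
        R = np.asarray(d["R"], dtype=np.float64)
        T = np.asarray(d["T"], dtype=np.float64)
    except KeyError as e:
        raise CalibrationError(f"calibration section '{name}' missing field {e}") from e
    if R.size != 9 or T.size != 3:
        raise CalibrationError(f"'{name}': R must have 9 entries (row-major) and T 3")
    return Extrinsics.from_values(R.reshape(3, 3), T)


def load_calibration(path: str | Path) -> CameraRig:
    """Load a YAML calibration file into a validated :class:`CameraRig`.

    Expected keys: ``depth``/``color`` with fx, fy, cx, cy (and optionally
    width, height); ``depth_to_color`` with R (9 numbers, row-major) and T
    (3 numbers, mm).  Optional: ``depth_to_world``, ``right_to_left``.
    """
    path = Path(path)
    if not path.exists():
        raise CalibrationError(f"calibration file not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise CalibrationError(f"{path}: not a mapping")
    for key in ("depth", "color", "depth_to_color"):
        if key not in doc:
            raise CalibrationError(f"{path}: missing required section '{key}'")
    return CameraRig(
        depth=_read_intrinsics(doc["depth"], "depth"),
        color=_read_intrinsics(doc["color"], "color"),
        depth_to_color=_read_extrinsics(doc["depth_to_color"], "depth_to_color"),
        depth_to_world=(
            _read_extrinsics(doc["depth_to_world"], "depth_to_world")
            if "depth_to_world" in doc
            else Extrinsics.identity()
        ),
        right_to_left=(
            _read_extrinsics(doc["right_to_left"], "right_to_left")
            if "right_to_left" in doc
            else None
        ),
    )


def default_calibration_path() -> Path:
    """Path of the calibration file shipped with the package (D455 rig)."""
    return Path(__file__).parent / "data" / "calib_d455_paper.yaml"


def load_default_calibration() -> CameraRig:
    """Load the shipped overhead D455 calibration."""
    with warnings.catch_warnings():
        # the shipped matrices are printed at 3 decimals; repair silently
        warnings.simplefilter("ignore")
        return load_calibration(default_calibration_path())
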