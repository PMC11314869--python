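"""Ground-truthed synthetic overhead depth scenes.

Renders the imaging geometry of an overhead RGB-D rig looking straight down
(nadir) at a tank: a flat, tilted, or bowl-shaped bottom with half-ellipsoid
fish phantoms resting on (or hovering above) it.  Every phantom has an
analytic volume, (2/3)*pi*a*b*c, so each downstream stage — segmentation,
bottom-depth estimation, thickness integration, mass regression — can be
validated against closed-form truth.

The camera sits at the origin of the depth-camera frame with its optical
axis pointing down (+z is range).  Rendering is per-pixel ray casting: a
pixel (u, v) casts the ray direction ((u-cx)/fx, (v-cy)/fy, 1), and the
recorded value is the z-coordinate (not the slant range) of the nearest
surface hit, matching what a stereo depth camera reports.

Sensor noise follows the stereo ranging model: the standard deviation grows
quadratically with range, anchored so that sigma(4 m) = 2% of 4 m for the
default model, the figure quoted for the D455 class of sensors.  A dropout
fraction of pixels is invalidated to mimic holes in real depth maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .camera_model import CameraRig, Intrinsics, load_default_calibration
from .frames import DepthFrame, write_depth_png

__all__ = [
    "FishPhantom",
    "PlanarBottom",
    "SphericalCapBottom",
    "NoiseModel",
    "SceneConfig",
    "render_scene",
    "add_depth_noise",
    "generate_detection_set",
]


@dataclass(frozen=True)
class FishPhantom:
    """Half-ellipsoid fish body: flat base down, dome up.

    semi_axes = (a, b, c) are the half-length, half-width and height in mm;
    ``center`` is the (x, y) world position of the base center; ``heading``
    rotates the long axis in the horizontal plane; ``rest_depth`` is the z
    of the flat base (the bottom surface depth when the fish rests on it).
    """

    semi_axes: tuple[float, float, float]
    center: tuple[float, float] = (0.0, 0.0)
    heading: float = 0.0
    rest_depth: float = 1000.0

    def __post_init__(self):
        if not all(s > 0 for s in self.semi_axes):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")

    @property
    def analytic_volume(self) -> float:
        """Closed-form volume of the half-ellipsoid, mm^3."""
        a, b, c = self.semi_axes
        return 2.0 / 3.0 * np.pi * a * b * c


@dataclass(frozen=True)
class PlanarBottom:
    """Tank bottom z = z0 + gx*x + gy*y (gx = gy = 0: flat)."""

    z0: float
    gx: float = 0.0
    gy: float = 0.0

    def depth_at(self, x: float, y: float) -> float:
        return self.z0 + self.gx * x + self.gy * y

    def ray_depth(self, dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
        # ray p(t) = t*(dx, dy, 1); solve z = z0 + gx*x + gy*y for t = z
        denom = 1.0 - self.gx * dx - self.gy * dy
        with np.errstate(divide="ignore"):
            t = np.where(denom > 1e-9, self.z0 / np.maximum(denom, 1e-9), np.inf)
        return np.where(t > 0, t, np.inf)


@dataclass(frozen=True)
class SphericalCapBottom:
    """Bowl-shaped bottom: interior of a sphere, deepest point at ``deepest_z``."""

    radius: float
    deepest_z: float
    center_xy: tuple[float, float] = (0.0, 0.0)

    def depth_at(self, x: float, y: float) -> float:
        x0, y0 = self.center_xy
        zc = self.deepest_z - self.radius
        r2 = (x - x0) ** 2 + (y - y0) ** 2
        if r2 >= self.radius**2:
            return np.nan
        return zc + np.sqrt(self.radius**2 - r2)

    def ray_depth(self, dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
        # far intersection with the sphere = the bowl's interior surface
        x0, y0 = self.center_xy
        zc = self.deepest_z - self.radius
        A = dx**2 + dy**2 + 1.0
        B = -2.0 * (dx * x0 + dy * y0 + zc)
        C = x0**2 + y0**2 + zc**2 - self.radius**2
        disc = B**2 - 4 * A * C
        with np.errstate(invalid="ignore"):
            t = (-B + np.sqrt(disc)) / (2 * A)
        t = np.where((disc >= 0) & (t > 0), t, np.inf)
        return t


@dataclass(frozen=True)
class NoiseModel:
    """Range-dependent Gaussian noise plus pixel dropout.

    sigma(z) = relative_sigma_at_4m * z^2 / 4000 mm, i.e. stereo error
    growing with the square of range and equal to ``relative_sigma_at_4m``
    of z at z = 4000 mm.
    """

    relative_sigma_at_4m: float = 0.02
    dropout_rate: float = 0.01

    def __post_init__(self):
        if not (0 <= self.relative_sigma_at_4m < 1 and 0 <= self.dropout_rate < 1):
            raise ValueError("noise parameters must lie in [0, 1)")

    def sigma(self, z: np.ndarray) -> np.ndarray:
        return self.relative_sigma_at_4m * np.asarray(z) ** 2 / 4000.0


@dataclass
class SceneConfig:
    """Full description of one synthetic capture."""

    camera_height: float = 1000.0
    bottom: PlanarBottom | SphericalCapBottom | None = None
    phantoms: list[FishPhantom] = field(default_factory=list)
    noise: NoiseModel = field(default_factory=NoiseModel)
    resolution: tuple[int, int] = (1280, 720)  # (width, height)
    seed: int = 0

    def __post_init__(self):
        if self.bottom is None:
            self.bottom = PlanarBottom(self.camera_height)


def _scaled_depth_intrinsics(rig: CameraRig, resolution: tuple[int, int]) -> Intrinsics:
    K = rig.depth
    w, h = resolution
    if K.width is None or K.width == w:
        return K
    factor = w / K.width
    if K.height is not None and int(round(K.height * factor)) != h:
        raise ValueError(
            f"resolution {resolution} is not an isotropic rescale of the "
            f"calibrated sensor ({K.width}x{K.height})"
        )
    return K.scaled(factor)


def _ellipsoid_hits(ph: FishPhantom, K: Intrinsics, shape: tuple[int, int]):
    """Ray-cast one half-ellipsoid; returns (vs, us, z) of hit pixels."""
    a, b, c = ph.semi_axes
    x0, y0 = ph.center
    H, W = shape
    # conservative pixel window from the plan-view bounding circle
    rmax = max(a, b)
    zmin = max(ph.rest_depth - c, 1.0)
    u_lo = int(np.floor(K.fx * (x0 - rmax) / zmin + K.cx)) - 2
    u_hi = int(np.ceil(K.fx * (x0 + rmax) / zmin + K.cx)) + 2
    v_lo = int(np.floor(K.fy * (y0 - rmax) / zmin + K.cy)) - 2
    v_hi = int(np.ceil(K.fy * (y0 + rmax) / zmin + K.cy)) + 2
    u_lo, u_hi = max(u_lo, 0), min(u_hi, W - 1)
    v_lo, v_hi = max(v_lo, 0), min(v_hi, H - 1)
    if u_lo > u_hi or v_lo > v_hi:
        return None
    us = np.arange(u_lo, u_hi + 1)
    vs = np.arange(v_lo, v_hi + 1)
    uu, vv = np.meshgrid(us, vs)
    dx = (uu - K.cx) / K.fx
    dy = (vv - K.cy) / K.fy

    ch, sh = np.cos(ph.heading), np.sin(ph.heading)
    # phantom frame: rotate by -heading about z, shift to the base center,
    # scale by the semi-axes; directions get only the linear part
    ux = (ch * dx + sh * dy) / a
    uy = (-sh * dx + ch * dy) / b
    uz = np.full_like(dx, 1.0 / c)
    wx = (ch * (-x0) + sh * (-y0)) / a
    wy = (-sh * (-x0) + ch * (-y0)) / b
    wz = -ph.rest_depth / c
    # |t*u + w| = 1
    A = ux**2 + uy**2 + uz**2
    B = 2.0 * (ux * wx + uy * wy + uz * wz)
    C = wx**2 + wy**2 + wz**2 - 1.0
    disc = B**2 - 4 * A * C
    hit = disc >= 0
    t = np.full_like(dx, np.inf)
    with np.errstate(invalid="ignore"):
        t1 = (-B - np.sqrt(np.where(hit, disc, 0.0))) / (2 * A)
    # first hit must be on the dome (z <= rest_depth) and in front of the camera
    valid = hit & (t1 > 0) & (t1 <= ph.rest_depth + 1e-9)
    t[valid] = t1[valid]
    return vv, uu, t


def render_scene(cfg: SceneConfig, rig: CameraRig | None = None
                 ) -> tuple[DepthFrame, list[np.ndarray], list[float]]:
    """Ray-cast a scene into a depth frame plus per-phantom truth.

    Returns ``(frame, masks, volumes)`` where ``masks[i]`` is the boolean
    grid of pixels whose nearest surface is phantom ``i`` and ``volumes[i]``
    its analytic volume in mm^3.  A phantom entirely outside the field of
    view yields an empty mask and a warning.
    """
    rig = rig or load_default_calibration()
    K = _scaled_depth_intrinsics(rig, cfg.resolution)
    W, H = cfg.resolution
    us = np.arange(W)
    vs = np.arange(H)
    dx = (us - K.cx) / K.fx
    dy = (vs - K.cy) / K.fy
    DX, DY = np.meshgrid(dx, dy)

    depth = cfg.bottom.ray_depth(DX, DY)
    owner = np.full((H, W), -1, dtype=np.int32)

    for i, ph in enumerate(cfg.phantoms):
        res = _ellipsoid_hits(ph, K, (H, W))
        if res is not None:
            vv, uu, t = res
            closer = t < depth[vv, uu]
            depth[vv[closer], uu[closer]] = t[closer]
            owner[vv[closer], uu[closer]] = i
        if res is None or not np.any(owner == i):
            warnings.warn(f"phantom {i} is outside the field of view", stacklevel=2)

    depth[~np.isfinite(depth)] = 0.0
    frame = DepthFrame(depth, {"camera_height": cfg.camera_height, "synthetic": True})
    masks = [owner == i for i in range(len(cfg.phantoms))]
    volumes = [ph.analytic_volume for ph in cfg.phantoms]
    return frame, masks, volumes


def add_depth_noise(frame: DepthFrame, model: NoiseModel, seed: int | np.random.Generator
                    ) -> DepthFrame:
    """Perturb valid pixels with range-dependent Gaussian noise and dropout.

    Deterministic: the same seed reproduces the same output bit for bit.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = frame.data.copy()
    valid = frame.valid
    z = data[valid]
    if z.size:
        noisy = z + rng.standard_normal(z.size) * model.sigma(z)
        data[valid] = np.maximum(noisy, 0.0)
        if model.dropout_rate > 0:
            drop = rng.random(z.size) < model.dropout_rate
            coords = np.nonzero(valid)
            data[coords[0][drop], coords[1][drop]] = 0.0
    return DepthFrame(data, dict(frame.meta))


def generate_detection_set(
    out_dir: str | Path,
    n_fish: int = 27,
    frames_per_fish: int = 60,
    size_range: tuple[float, float] = (80.0, 250.0),
    seed: int = 0,
    resolution: tuple[int, int] = (640, 360),
    density_g_cm3: float = 1.05,
    noise: NoiseModel | None = None,
    camera_height_range: tuple[float, float] = (800.0, 1200.0),
    bottom_tilt: float = 0.02,
    clearance: float = 0.0,
    rig: CameraRig | None = None,
    write_rgb: bool = False,
) -> pd.DataFrame:
    """Render a full detection set: one phantom per fish, many poses each.

    Each fish is assigned a fixed half-ellipsoid (half-length drawn from
    ``size_range``; width and height proportioned like a sturgeon body) and
    rendered ``frames_per_fish`` times at random positions, headings,
    gentle bottom tilts and camera heights in ``camera_height_range``.
    True mass is density * analytic volume.  Layout::

        out_dir/depth/<fish>_<frame>.png   16-bit depth, mm
        out_dir/mask/<fish>_<frame>.png    8-bit truth mask, 0/255
        out_dir/truth.csv                  fish_id, a, b, c, volume_mm3,
                                           mass_g, density

    Returns the truth table.  ``clearance`` lifts every fish that many mm
    off the bottom, deliberately violating the resting assumption.
    """
    if n_fish < 1:
        raise ValueError("n_fish must be >= 1")
    out_dir = Path(out_dir)
    depth_dir = out_dir / "depth"
    mask_dir = out_dir / "mask"
    depth_dir.mkdir(parents=True, exist_ok=True)
    mask_dir.mkdir(parents=True, exist_ok=True)
    rgb_dir = out_dir / "rgb"
    if write_rgb:
        rgb_dir.mkdir(parents=True, exist_ok=True)

    rig = rig or load_default_calibration()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    K = _scaled_depth_intrinsics(rig, resolution)
    W, H = resolution

    rows = []
    for i in range(n_fish):
        a = rng.uniform(*size_range)
        b = a * rng.uniform(0.22, 0.28)
        c = a * rng.uniform(0.15, 0.20)
        ph_volume = 2.0 / 3.0 * np.pi * a * b * c
        mass = density_g_cm3 * ph_volume / 1000.0
        fish_id = f"f{i:03d}"
        rows.append(
            dict(fish_id=fish_id, a=a, b=b, c=c,
                 volume_mm3=ph_volume, mass_g=mass, density=density_g_cm3)
        )
        for j in range(frames_per_fish):
            z0 = rng.uniform(*camera_height_range)
            gx = rng.uniform(-bottom_tilt, bottom_tilt)
            gy = rng.uniform(-bottom_tilt, bottom_tilt)
            zmin = z0 - c - clearance
            rmax = max(a, b)
            half_x = (min(K.cx, W - 1 - K.cx) - 4) * zmin / K.fx - rmax
            half_y = (min(K.cy, H - 1 - K.cy) - 4) * zmin / K.fy - rmax
            if half_x <= 0 or half_y <= 0:
                raise ValueError("fish too large for the field of view at this height")
            x = rng.uniform(-half_x, half_x)
            y = rng.uniform(-half_y, half_y)
            bottom = PlanarBottom(z0, gx, gy)
            ph = FishPhantom(
                (a, b, c), (x, y), rng.uniform(0, 2 * np.pi),
                bottom.depth_at(x, y) - clearance,
            )
            cfg = SceneConfig(camera_height=z0, bottom=bottom, phantoms=[ph],
                              noise=noise, resolution=resolution)
            with warnings.catch_warnings():
                warnings.simplefilter("error")  # placement must stay in FOV
                frame, masks, _ = render_scene(cfg, rig)
            frame = add_depth_noise(frame, noise, rng)
            stem = f"{fish_id}_{j:03d}.png"
            write_depth_png(frame, depth_dir / stem)
            iio.imwrite(mask_dir / stem, (masks[0].astype(np.uint8) * 255))
            if write_rgb:
                # flat-shaded stub: mask mid-gray on dark background
                rgb = np.full((H, W, 3), 40, dtype=np.uint8)
                rgb[masks[0]] = 150
                iio.imwrite(rgb_dir / stem, rgb)

    truth = pd.DataFrame(rows)
    truth.to_csv(out_dir / "truth.csv", index=False, float_format="%.6f")
    return truth
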