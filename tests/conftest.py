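import numpy as np
import pytest

from fishvol.camera_model import CameraRig, Extrinsics, Intrinsics, load_default_calibration


@pytest.fixture(scope="session")
def rig() -> CameraRig:
    """The shipped overhead D455 calibration."""
    return load_default_calibration()


@pytest.fixture(scope="session")
def K_depth(rig) -> Intrinsics:
    return rig.depth


@pytest.fixture(scope="session")
def K_rgb(rig) -> Intrinsics:
    return rig.color


@pytest.fixture
def tiny_rig() -> CameraRig:
    """A small 64x64 rig for fast synthetic renders."""
    K = Intrinsics(fx=100.0, fy=100.0, cx=31.5, cy=31.5, width=64, height=64)
    return CameraRig(depth=K, color=K, depth_to_color=Extrinsics.identity())


@pytest.fixture(scope="session")
def small_detection_set(tmp_path_factory):
    """A 3-fish x 4-frame rendered detection set shared by pipeline tests."""
    from fishvol.synthetic_scene import generate_detection_set

    out = tmp_path_factory.mktemp("detset")
    truth = generate_detection_set(out, n_fish=3, frames_per_fish=4, seed=11)
    return out, truth


def brute_force_disk_ring(grid: np.ndarray, width: int) -> np.ndarray:
    """Oracle: dilate by shifting the mask to every offset within the disk."""
    H, W = grid.shape
    dil = np.zeros_like(grid)
    for dy in range(-width, width + 1):
        for dx in range(-width, width + 1):
            if dx * dx + dy * dy <= width * width:
                shifted = np.zeros_like(grid)
                ys, xs = np.nonzero(grid)
                ys2, xs2 = ys + dy, xs + dx
                ok = (ys2 >= 0) & (ys2 < H) & (xs2 >= 0) & (xs2 < W)
                shifted[ys2[ok], xs2[ok]] = True
                dil |= shifted
    return dil & ~grid
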