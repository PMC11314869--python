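"""Bottom-depth estimation, thickness maps, and volume integration."""

from fractions import Fraction

import numpy as np
import pytest
from scipy.integrate import quad

from fishvol.camera_model import Intrinsics
from fishvol.errors import QCRejection
from fishvol.frames import DepthFrame
from fishvol.segmentation_io import FishMask, extract_ring
from fishvol.synthetic_scene import FishPhantom, PlanarBottom, SceneConfig, render_scene
from fishvol.volume import (
    correct_volume,
    estimate_bottom_depth,
    estimate_frame_volume,
    fish_distance,
    integrate_volume_metric,
    integrate_volume_paper,
    thickness_map,
)


@pytest.fixture
def flat_frame():
    data = np.full((60, 60), 1000.0)
    grid = np.zeros((60, 60), dtype=bool)
    grid[20:40, 20:40] = True
    return DepthFrame(data), FishMask(grid)


class TestBottomDepth:
    def test_flat_bottom_exact(self, flat_frame):
        frame, mask = flat_frame
        ring = extract_ring(mask, 3)
        assert estimate_bottom_depth(frame, ring) == 1000.0

    def test_tilted_plane_symmetric_ring_unbiased(self):
        # z = 1000 + 0.1*(u - u0); a ring symmetric about u0 averages out
        # the tilt, so the estimate should equal the depth at the center
        u = np.arange(100)
        data = np.tile(1000.0 + 0.1 * (u - 49.5), (100, 1))
        grid = np.zeros((100, 100), dtype=bool)
        grid[40:60, 40:60] = True
        ring = extract_ring(FishMask(grid), 5)
        est = estimate_bottom_depth(DepthFrame(data), ring)
        assert est == pytest.approx(1000.0, abs=0.1)

    def test_all_invalid_ring_rejected(self, flat_frame):
        frame, mask = flat_frame
        ring = extract_ring(mask, 3)
        dead = DepthFrame(np.zeros((60, 60)))
        with pytest.raises(QCRejection) as exc:
            estimate_bottom_depth(dead, ring)
        assert exc.value.reason == "ring-invalid"

    def test_median_option(self, flat_frame):
        frame, mask = flat_frame
        frame.data[21, 19] = 5000.0  # outlier in the ring
        ring = extract_ring(mask, 3)
        med = estimate_bottom_depth(frame, ring, method="median")
        assert med == 1000.0


class TestThicknessMap:
    def test_basic_difference(self, flat_frame):
        frame, mask = flat_frame
        frame.data[25, 25] = 950.0
        t = thickness_map(frame, mask, bottom=1000.0)
        assert t.grid[25, 25] == 50.0
        assert t.n_clamped == 0

    def test_negative_thickness_clamped_and_counted(self, flat_frame):
        frame, mask = flat_frame
        frame.data[25, 25] = 1003.0
        t = thickness_map(frame, mask, bottom=1000.0)
        assert t.grid[25, 25] == 0.0
        assert t.n_clamped == 1

    def test_surface_at_bottom_gives_zero_total(self, flat_frame):
        frame, mask = flat_frame
        t = thickness_map(frame, mask, bottom=1000.0)
        assert t.grid.sum() == 0.0

    def test_excess_invalid_pixels_rejected(self, flat_frame):
        frame, mask = flat_frame
        frame.data[20:40, 20:34] = 0.0  # >50% of the mask loses depth
        with pytest.raises(QCRejection) as exc:
            thickness_map(frame, mask, bottom=1000.0)
        assert exc.value.reason == "invalid-depth-excess"


class TestIntegration:
    K = Intrinsics(648.890, 648.890, 637.205, 365.610)

    def _single_pixel(self, z=800.0, bottom=850.0):
        data = np.full((9, 9), bottom)
        data[4, 4] = z
        grid = np.zeros((9, 9), dtype=bool)
        grid[4, 4] = True
        frame = DepthFrame(data)
        return frame, thickness_map(frame, FishMask(grid), bottom)

    def test_single_pixel_matches_cone_integral(self):
        # oracle: volume of the pixel's viewing cone between the surface
        # and the bottom, integral of z^2/(fx*fy) dz over [800, 850]
        frame, t = self._single_pixel()
        est = integrate_volume_metric(t, frame, self.K)
        oracle, _ = quad(lambda z: z**2 / (self.K.fx * self.K.fy), 800.0, 850.0)
        assert est.volume_mm3 == pytest.approx(oracle, rel=1e-12)
        assert est.n_pixels == 1

    def test_zero_thickness_gives_zero_volume(self, flat_frame):
        frame, mask = flat_frame
        t = thickness_map(frame, mask, bottom=1000.0)
        est = integrate_volume_metric(t, frame, self.K)
        assert est.volume_mm3 == 0.0

    def test_paper_mode_at_reference_distance_is_constant_footprint(self):
        frame, t = self._single_pixel()
        est = integrate_volume_paper(t, 800.0, 800.0, self.K)
        assert est.volume_mm3 == pytest.approx(
            50.0 * 800.0**2 / (self.K.fx * self.K.fy), rel=1e-12)

    def test_paper_mode_distance_correction_factor(self):
        frame, t = self._single_pixel()
        near = integrate_volume_paper(t, 800.0, 800.0, self.K)
        far = integrate_volume_paper(t, 1600.0, 800.0, self.K)
        assert far.volume_mm3 == pytest.approx(4 * near.volume_mm3, rel=1e-12)

    def test_thickness_scaling_is_linear_in_both_modes(self):
        frame, t = self._single_pixel()
        v1 = integrate_volume_metric(t, frame, self.K).volume_mm3
        p1 = integrate_volume_paper(t, 820.0, 800.0, self.K).volume_mm3
        t.grid = t.grid * 3.0
        assert integrate_volume_metric(t, frame, self.K).volume_mm3 == pytest.approx(
            3.0 * v1, rel=1e-12)
        assert integrate_volume_paper(t, 820.0, 800.0, self.K).volume_mm3 == pytest.approx(
            3.0 * p1, rel=1e-12)


class TestCorrectVolume:
    def test_factor_of_four(self):
        assert correct_volume(100.0, 800.0, 1600.0) == 400.0

    def test_same_distance_is_identity(self):
        assert correct_volume(123.4, 900.0, 900.0) == 123.4

    def test_inverse_composition_exact_on_rationals(self):
        V = Fraction(37699, 100)
        a, b = Fraction(817), Fraction(1093)
        assert correct_volume(correct_volume(V, a, b), b, a) == V

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            correct_volume(100.0, 0.0, 900.0)


class TestPhantomAccuracy:
    """End-to-end volume accuracy on analytically known half-ellipsoids."""

    @staticmethod
    def _estimate(rig, a, b, c, height, mode="metric", y_ref=None):
        ph = FishPhantom((a, b, c), center=(40.0, -25.0), heading=0.5,
                         rest_depth=height)
        cfg = SceneConfig(camera_height=height, bottom=PlanarBottom(height),
                          phantoms=[ph], resolution=(1280, 720))
        frame, masks, vols = render_scene(cfg, rig)
        est = estimate_frame_volume(frame, FishMask(masks[0]), rig.depth,
                                    mode=mode, y_ref=y_ref)
        return est, vols[0]

    def test_metric_mode_matches_closed_form(self, rig):
        est, true = self._estimate(rig, 150.0, 40.0, 30.0, 1000.0)
        assert est.volume_mm3 == pytest.approx(true, rel=0.03)

    def test_paper_mode_matches_closed_form(self, rig):
        est, true = self._estimate(rig, 150.0, 40.0, 30.0, 1000.0,
                                   mode="paper", y_ref=1000.0)
        assert est.volume_mm3 == pytest.approx(true, rel=0.03)

    def test_bottom_clearance_inflates_by_plan_area(self, rig):
        # a fish hovering h mm above the bottom picks up h * (plan area)
        # of phantom water below it
        a, b, c, h = 150.0, 40.0, 30.0, 20.0
        resting, _ = self._estimate(rig, a, b, c, 1000.0)
        ph = FishPhantom((a, b, c), center=(40.0, -25.0), heading=0.5,
                         rest_depth=1000.0 - h)
        cfg = SceneConfig(camera_height=1000.0, bottom=PlanarBottom(1000.0),
                          phantoms=[ph], resolution=(1280, 720))
        frame, masks, _ = render_scene(cfg, rig)
        lifted = estimate_frame_volume(frame, FishMask(masks[0]), rig.depth)
        inflation = lifted.volume_mm3 - resting.volume_mm3
        assert inflation == pytest.approx(h * np.pi * a * b, rel=0.15)

    def test_fish_distance_is_mid_column(self):
        data = np.full((9, 9), 1000.0)
        data[4, 4] = 940.0
        grid = np.zeros((9, 9), dtype=bool)
        grid[4, 4] = True
        t = thickness_map(DepthFrame(data), FishMask(grid), 1000.0)
        assert fish_distance(t) == pytest.approx(970.0)
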