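"""Ray-cast scene renderer, noise model, and detection-set generator."""

import numpy as np
import pytest

from fishvol.frames import read_depth_png
from fishvol.synthetic_scene import (
    FishPhantom,
    NoiseModel,
    PlanarBottom,
    SceneConfig,
    SphericalCapBottom,
    add_depth_noise,
    generate_detection_set,
    render_scene,
)


class TestRenderScene:
    def test_empty_scene_is_constant_plane(self, tiny_rig):
        cfg = SceneConfig(camera_height=1000.0, bottom=PlanarBottom(1000.0),
                          resolution=(64, 64))
        frame, masks, vols = render_scene(cfg, tiny_rig)
        # principal ray depth is exactly 1000; oblique rays also record
        # z-depth (not slant range), so the whole plane reads 1000
        assert frame.data == pytest.approx(1000.0)
        assert masks == [] and vols == []

    def test_analytic_volume_closed_form(self):
        ph = FishPhantom((150.0, 40.0, 30.0))
        assert ph.analytic_volume == pytest.approx(2 / 3 * np.pi * 150 * 40 * 30,
                                                   rel=1e-12)
        assert ph.analytic_volume == pytest.approx(376991.1, abs=0.1)

    def test_apex_depth_is_height_minus_thickness(self, rig):
        ph = FishPhantom((150.0, 40.0, 30.0), center=(0.0, 0.0), rest_depth=1000.0)
        cfg = SceneConfig(camera_height=1000.0, bottom=PlanarBottom(1000.0),
                          phantoms=[ph], resolution=(1280, 720))
        frame, masks, _ = render_scene(cfg, rig)
        u0 = int(round(rig.depth.cx))
        v0 = int(round(rig.depth.cy))
        # principal pixel looks straight down at the apex
        assert frame.data[v0, u0] == pytest.approx(970.0, abs=0.05)
        assert frame.data[masks[0]].min() >= 970.0 - 1e-6

    def test_mask_area_matches_plan_view_ellipse(self, rig):
        a, b = 150.0, 40.0
        ph = FishPhantom((a, b, 30.0), center=(0.0, 0.0), heading=0.7,
                         rest_depth=1000.0)
        cfg = SceneConfig(camera_height=1000.0, bottom=PlanarBottom(1000.0),
                          phantoms=[ph], resolution=(1280, 720))
        frame, masks, _ = render_scene(cfg, rig)
        footprint = 1000.0**2 / (rig.depth.fx * rig.depth.fy)
        expected_px = np.pi * a * b / footprint
        assert masks[0].sum() == pytest.approx(expected_px, rel=0.02)

    def test_spherical_bowl_deepest_at_center(self, tiny_rig):
        bottom = SphericalCapBottom(radius=2000.0, deepest_z=1000.0)
        cfg = SceneConfig(camera_height=1000.0, bottom=bottom, resolution=(64, 64))
        frame, _, _ = render_scene(cfg, tiny_rig)
        center = frame.data[31:33, 31:33].max()
        assert center == pytest.approx(1000.0, abs=0.5)
        assert frame.data[frame.valid].max() <= 1000.0 + 1e-9

    def test_out_of_view_phantom_warns_with_empty_mask(self, tiny_rig):
        ph = FishPhantom((50.0, 20.0, 10.0), center=(10_000.0, 0.0),
                         rest_depth=1000.0)
        cfg = SceneConfig(camera_height=1000.0, bottom=PlanarBottom(1000.0),
                          phantoms=[ph], resolution=(64, 64))
        with pytest.warns(UserWarning, match="field of view"):
            _, masks, _ = render_scene(cfg, tiny_rig)
        assert masks[0].sum() == 0

    def test_nonpositive_semi_axis_rejected(self):
        with pytest.raises(ValueError):
            FishPhantom((0.0, 40.0, 30.0))


class TestNoiseModel:
    def test_sigma_anchored_at_two_percent_of_4m(self):
        model = NoiseModel()
        assert model.sigma(4000.0) == pytest.approx(80.0)
        assert model.sigma(1000.0) == pytest.approx(5.0)  # 0.02 * 1000^2 / 4000

    def test_zero_noise_is_identity(self, tiny_rig):
        cfg = SceneConfig(bottom=PlanarBottom(1000.0), resolution=(64, 64))
        frame, _, _ = render_scene(cfg, tiny_rig)
        out = add_depth_noise(frame, NoiseModel(0.0, 0.0), seed=1)
        np.testing.assert_array_equal(out.data, frame.data)

    def test_same_seed_reproduces_bitwise(self, tiny_rig):
        cfg = SceneConfig(bottom=PlanarBottom(1000.0), resolution=(64, 64))
        frame, _, _ = render_scene(cfg, tiny_rig)
        a = add_depth_noise(frame, NoiseModel(), seed=9)
        b = add_depth_noise(frame, NoiseModel(), seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    def test_noise_is_unbiased(self, rig):
        cfg = SceneConfig(bottom=PlanarBottom(1000.0), resolution=(1280, 720))
        frame, _, _ = render_scene(cfg, rig)
        noisy = add_depth_noise(frame, NoiseModel(dropout_rate=0.0), seed=3)
        diff = noisy.data - frame.data
        n = diff.size
        assert n >= 1e5
        sigma = NoiseModel().sigma(1000.0)
        assert abs(diff.mean()) < 3 * sigma / np.sqrt(n)

    def test_dropout_invalidates_expected_fraction(self, tiny_rig):
        cfg = SceneConfig(bottom=PlanarBottom(1000.0), resolution=(64, 64))
        frame, _, _ = render_scene(cfg, tiny_rig)
        out = add_depth_noise(frame, NoiseModel(0.0, 0.25), seed=5)
        frac = 1.0 - out.valid.mean()
        assert frac == pytest.approx(0.25, abs=0.03)

    def test_parameters_validated(self):
        with pytest.raises(ValueError):
            NoiseModel(relative_sigma_at_4m=1.5)


class TestGenerateDetectionSet:
    def test_counts_and_layout(self, small_detection_set):
        out, truth = small_detection_set
        assert len(truth) == 3
        assert len(list((out / "depth").glob("*.png"))) == 12
        assert len(list((out / "mask").glob("*.png"))) == 12
        assert set(truth.columns) >= {"fish_id", "a", "b", "c", "volume_mm3",
                                      "mass_g", "density"}

    def test_true_mass_is_density_times_volume(self, small_detection_set):
        _, truth = small_detection_set
        np.testing.assert_allclose(
            truth.mass_g, truth.density * truth.volume_mm3 / 1000.0, rtol=1e-6)

    def test_same_seed_is_byte_identical(self, tmp_path):
        for d in ("r1", "r2"):
            generate_detection_set(tmp_path / d, n_fish=2, frames_per_fish=2, seed=5)
        assert ((tmp_path / "r1" / "truth.csv").read_bytes()
                == (tmp_path / "r2" / "truth.csv").read_bytes())
        name = "f000_000.png"
        assert ((tmp_path / "r1" / "depth" / name).read_bytes()
                == (tmp_path / "r2" / "depth" / name).read_bytes())

    def test_degenerate_size_range_gives_equal_lengths(self, tmp_path):
        truth = generate_detection_set(tmp_path, n_fish=3, frames_per_fish=1,
                                       size_range=(120.0, 120.0), seed=2)
        assert truth.a.nunique() == 1

    def test_masks_are_consistent_with_depth(self, small_detection_set):
        # mask pixels must stand proud of the surrounding bottom
        out, _ = small_detection_set
        import imageio.v3 as iio

        name = sorted((out / "depth").glob("*.png"))[0].name
        frame = read_depth_png(out / "depth" / name)
        mask = iio.imread(out / "mask" / name) > 0
        inside = frame.data[mask & frame.valid]
        outside = frame.data[~mask & frame.valid]
        assert np.median(inside) < np.median(outside)

    def test_n_fish_validated(self, tmp_path):
        with pytest.raises(ValueError):
            generate_detection_set(tmp_path, n_fish=0)
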