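import numpy as np
import pytest

import leafps as lp
from leafps.exceptions import ConfigurationError
from leafps.leaf import (
    auto_opening_radius,
    blade_inclination,
    blade_petiole_lengths,
    leaf_landmarks,
    leaf_record,
    split_blade_petiole,
)


@pytest.fixture()
def toy_leaf():
    """Disc blade (r=20 px, centre (60, 60)) on a 4-px-wide stem running
    down to row 110; origin at the stem base (110, 60)."""
    mask = np.zeros((120, 120), dtype=bool)
    rr, cc = np.ogrid[:120, :120]
    mask[(rr - 60) ** 2 + (cc - 60) ** 2 <= 20**2] = True
    mask[80:111, 58:62] = True
    return mask


class TestSplitBladePetiole:
    def test_toy_leaf_splits_at_junction(self, toy_leaf):
        blade, petiole = split_blade_petiole(toy_leaf, 6)
        assert blade.sum() == pytest.approx(np.pi * 400, rel=0.02)
        # petiole is the stem below the disc
        pet_rows = np.argwhere(petiole)[:, 0]
        assert np.median(pet_rows) > 80
        # exact partition
        np.testing.assert_array_equal(blade | petiole, toy_leaf)
        assert not (blade & petiole).any()

    def test_disc_without_stem_flags_empty_petiole(self):
        mask = np.zeros((80, 80), dtype=bool)
        rr, cc = np.ogrid[:80, :80]
        mask[(rr - 40) ** 2 + (cc - 40) ** 2 <= 20**2] = True
        blade, petiole = split_blade_petiole(mask, 6)
        # only isolated rasterization residue may remain
        assert petiole.sum() < 0.01 * mask.sum()
        lm = leaf_landmarks(blade, petiole, (78, 40))
        assert lm.petiole_empty

    def test_wide_stem_survives_opening(self):
        # stem width 14 > 2 * radius 6: the opening keeps it in the blade
        mask = np.zeros((140, 140), dtype=bool)
        rr, cc = np.ogrid[:140, :140]
        mask[(rr - 60) ** 2 + (cc - 60) ** 2 <= 25**2] = True
        mask[80:130, 53:67] = True
        blade, petiole = split_blade_petiole(mask, 6)
        assert petiole.sum() < 0.02 * mask.sum()

    def test_monotone_blade_shrinkage_with_radius(self, toy_leaf):
        areas = [split_blade_petiole(toy_leaf, r)[0].sum() for r in (3, 6, 9, 11)]
        assert all(b <= a for a, b in zip(areas, areas[1:]))

    def test_excessive_radius_raises(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[18:22, 18:22] = True
        with pytest.raises(ConfigurationError):
            split_blade_petiole(mask, 11)

    def test_auto_radius_bounds(self):
        assert auto_opening_radius(50) == 3
        assert auto_opening_radius(100000) == 11
        assert 3 <= auto_opening_radius(4000) <= 11


class TestLandmarks:
    def test_toy_leaf_junction_and_tip(self, toy_leaf):
        blade, petiole = split_blade_petiole(toy_leaf, 6)
        lm = leaf_landmarks(blade, petiole, (110, 60))
        assert lm.P_B[0] == pytest.approx(80, abs=2)
        assert lm.P_B[1] == pytest.approx(60, abs=2)
        assert lm.P_T[0] == pytest.approx(40, abs=1)
        assert lm.P_T[1] == pytest.approx(60, abs=1)

    def test_no_petiole_fallback_is_nearest_boundary(self):
        mask = np.zeros((80, 80), dtype=bool)
        rr, cc = np.ogrid[:80, :80]
        mask[(rr - 40) ** 2 + (cc - 40) ** 2 <= 20**2] = True
        blade, petiole = split_blade_petiole(mask, 6)
        lm = leaf_landmarks(blade, petiole, (78, 40))
        assert lm.petiole_empty
        # boundary pixel nearest an origin below the disc
        assert lm.P_B[0] == pytest.approx(60, abs=1.5)
        assert lm.P_B[1] == pytest.approx(40, abs=1.5)

    def test_symmetric_blade_tip_on_axis(self, toy_leaf):
        blade, petiole = split_blade_petiole(toy_leaf, 6)
        lm = leaf_landmarks(blade, petiole, (110, 60))
        assert abs(lm.P_T[1] - 60) <= 1


class TestLengthsAndInclination:
    def test_toy_leaf_chord_lengths(self, toy_leaf):
        blade, petiole = split_blade_petiole(toy_leaf, 6)
        lm = leaf_landmarks(blade, petiole, (110, 60))
        cam = lp.CameraModel(pixel_scale=1.0, image_shape=(120, 120))
        L = blade_petiole_lengths(lm, cam)
        assert L.blade_length_mm == pytest.approx(40, abs=2)
        assert L.petiole_length_mm == pytest.approx(30, abs=2)
        assert L.ratio == pytest.approx(4 / 3, abs=0.1)

    def test_empty_petiole_flags_undefined_ratio(self):
        from leafps.leaf import LeafLandmarks

        lm = LeafLandmarks((50.0, 40.0), (30.0, 40.0), (10.0, 40.0), petiole_empty=True)
        cam = lp.CameraModel(pixel_scale=1.0, image_shape=(64, 64))
        L = blade_petiole_lengths(lm, cam)
        assert not L.ratio_defined
        assert np.isnan(L.ratio)

    def test_flat_tilted_blade_both_methods_agree(self, rig8):
        cam = lp.CameraModel(pixel_scale=1.0, image_shape=(129, 129))
        scene = lp.make_flat_target(3600.0, 20.0, 0.0, cam)
        imgs = lp.render_ps(scene, rig8, noise_sd=0.0, seed=0, camera=cam)
        nm = lp.solve_normals(imgs)
        mask = scene.labels > 0
        from leafps.leaf import LeafLandmarks

        lm = LeafLandmarks((64.0, 64.0), (64.0, 45.0), (64.0, 80.0))
        line = blade_inclination(nm, mask, lm, "line")
        mean = blade_inclination(nm, mask, lm, "mean")
        assert line == pytest.approx(20.0, abs=0.3)
        assert mean == pytest.approx(20.0, abs=0.3)

    def test_horizontal_blade_is_flat(self, rig8):
        cam = lp.CameraModel(pixel_scale=1.0, image_shape=(129, 129))
        scene = lp.make_flat_target(3600.0, 0.0, 0.0, cam)
        imgs = lp.render_ps(scene, rig8, noise_sd=0.0, seed=0, camera=cam)
        nm = lp.solve_normals(imgs)
        assert blade_inclination(nm, scene.labels > 0) == pytest.approx(0.0, abs=0.2)

    def test_domed_blade_inclination_positive_at_zero_nastic(self, rig8):
        """A convex blade reads a positive mean inclination even when its
        nastic (rigid-tilt) angle is zero."""
        spec = lp.RosetteSpec(
            inclination_baseline_deg=0.0, inclination_amplitude_deg=0.0
        )
        cam = lp.CameraModel(pixel_scale=0.2, image_shape=(161, 161))
        scene = lp.make_rosette_series(spec, [0.0], cam)[0]
        nm = lp.solve_normals(lp.render_ps(scene, rig8, 0.0, 0, camera=cam))
        blade, petiole = split_blade_petiole(scene.labels == 1, 3)
        assert blade_inclination(nm, blade) > 1.0

    def test_degenerate_landmarks_fall_back_to_mean(self, rig8):
        cam = lp.CameraModel(pixel_scale=1.0, image_shape=(129, 129))
        scene = lp.make_flat_target(3600.0, 20.0, 0.0, cam)
        nm = lp.solve_normals(lp.render_ps(scene, rig8, 0.0, 0, camera=cam))
        from leafps.leaf import LeafLandmarks

        lm = LeafLandmarks((64.0, 64.0), (64.0, 64.0), (64.0, 64.0))
        with pytest.warns(UserWarning):
            val = blade_inclination(nm, scene.labels > 0, lm, "line")
        assert val == pytest.approx(20.0, abs=0.3)


class TestGeneratorRecovery:
    def test_blade_petiole_ratio_recovered(self, rig8):
        """The generator builds leaves with blade:petiole chord ratio 2:1
        (blade chord 2a = 5 mm, petiole 2.5 mm); the landmark pipeline
        recovers it within 10% on a flat-lying leaf."""
        spec = lp.RosetteSpec(
            inclination_baseline_deg=0.0, inclination_amplitude_deg=0.0
        )
        cam = lp.CameraModel(pixel_scale=0.1, image_shape=(161, 161))
        scene = lp.make_rosette_series(spec, [0.0], cam)[0]
        nm = lp.solve_normals(lp.render_ps(scene, rig8, 0.0, 0, camera=cam))
        rec = leaf_record(1, scene.labels == 1, nm, cam, scene.meta["origin_px"])
        expected = 2 * spec.blade_semi_axes_mm[0] / spec.petiole_length_mm
        assert rec["blade_petiole_ratio"] == pytest.approx(expected, rel=0.10)

    def test_growth_rate_recovered_from_blade_areas(self, rig8):
        spec = lp.RosetteSpec(inclination_amplitude_deg=0.0)
        cam = lp.CameraModel(pixel_scale=0.25, image_shape=(161, 161))
        times = np.arange(0, 48.5, 4.0)
        scenes = lp.make_rosette_series(spec, times, cam)
        areas = []
        for scene in scenes:
            nm = lp.solve_normals(lp.render_ps(scene, rig8, 0.0, 0, camera=cam))
            blade, _ = split_blade_petiole(scene.labels == 1, 3)
            areas.append(float(lp.projected_area_3d(blade, nm, cam)))
        rate = np.polyfit(times, np.log(areas), 1)[0]
        assert rate == pytest.approx(0.01, rel=0.05)
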