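"""Cube conditioning: normalization, SAM segmentation, reduction, EI."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spectromics.cohort import CohortDesign, TumorTrajectory, generate_scene, render_cube
from spectromics.grids import WavelengthGrid, default_grid
from spectromics.preprocessing import (
    DegenerateReferenceError,
    EIWindows,
    HyperCube,
    erythema_index,
    normalize_reflectance,
    prepare_ei_display,
    reduce_cube,
    remove_background,
    spectral_angle,
)


class TestNormalization:
    def test_raw_equals_white_gives_one(self):
        raw = np.full((4, 5, 3), 9.0)
        cube = normalize_reflectance(raw, 1.0, 9.0)
        assert np.all(cube.data == 1.0)
        assert cube.stage == "normalized"

    def test_raw_equals_dark_gives_zero(self):
        raw = np.full((4, 5, 3), 1.0)
        cube = normalize_reflectance(raw, 1.0, 9.0)
        assert np.all(cube.data == 0.0)

    def test_midpoint_arithmetic(self):
        cube = normalize_reflectance(np.full((2, 2, 2), 5.0), 1.0, 9.0)
        assert np.all(cube.data == 0.5)

    def test_degenerate_reference_rejected(self):
        with pytest.raises(DegenerateReferenceError):
            normalize_reflectance(np.ones((2, 2, 2)), 2.0, 2.0)

    def test_affine_invariance(self, rng):
        """Gain and offset applied consistently to raw/dark/white cancel."""
        raw = rng.uniform(2.0, 8.0, (3, 4, 5))
        dark, white = 1.0, 10.0
        base = normalize_reflectance(raw, dark, white)
        gained = normalize_reflectance(3.0 * raw + 2.0, 3.0 * dark + 2.0,
                                       3.0 * white + 2.0)
        np.testing.assert_allclose(gained.data, base.data, rtol=1e-12)


class TestSpectralAngle:
    def test_scale_invariance_and_symmetry(self):
        s1 = np.array([0.2, 0.5, 0.9])
        s2 = np.array([0.4, 0.1, 0.3])
        assert spectral_angle(s1, 3 * s1) == pytest.approx(0.0, abs=1e-6)
        assert spectral_angle(s1, s2) == pytest.approx(
            spectral_angle(s2, s1))
        assert spectral_angle(2.5 * s1, s2) == pytest.approx(
            spectral_angle(s1, s2))

    def test_closed_forms(self):
        assert spectral_angle([1, 0], [0, 1]) == pytest.approx(90.0)
        assert spectral_angle([1, 0], [1, 1]) == pytest.approx(45.0)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            spectral_angle([0, 0], [1, 1])

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=8),
           st.floats(0.1, 10.0))
    def test_angle_in_range_and_scale_free(self, vals, c):
        s1 = np.array(vals)
        s2 = s1[::-1].copy()
        a = spectral_angle(s1, s2)
        assert 0.0 <= a <= 180.0
        assert spectral_angle(c * s1, s2) == pytest.approx(a, abs=1e-6)


class TestBackgroundRemoval:
    def test_own_spectrum_reference_keeps_everything(self, rng):
        spec = rng.uniform(0.2, 0.8, 8)
        data = np.tile(spec, (6, 7, 1))
        cube = HyperCube(data, WavelengthGrid(np.arange(8.0) + 1),
                         stage="normalized")
        mask = remove_background(cube, reference_spectrum=spec, center=False)
        assert mask.tissue.all()

    def test_synthetic_scene_matches_ground_truth(self, lut):
        """Rendered phantom: SAM segmentation agrees with the generator's
        mask on at least 99% of pixels."""
        design = CohortDesign()
        rng = np.random.default_rng(5)
        maps, mask = generate_scene(0, 9, design, TumorTrajectory(), rng)
        rend = render_cube(maps, mask, design, rng, lut=lut)
        norm = normalize_reflectance(rend["raw"].data, rend["dark"],
                                     rend["white"], grid=rend["raw"].grid)
        red = reduce_cube(norm, spatial_bin=design.oversample)
        seg = remove_background(red)
        agreement = (seg.tissue == mask.tissue).mean()
        assert agreement >= 0.99

    def test_zero_threshold_keeps_almost_nothing(self, rng):
        data = np.abs(rng.standard_normal((10, 10, 8))) + 0.01
        cube = HyperCube(data, WavelengthGrid(np.arange(8.0) + 1),
                         stage="normalized")
        with pytest.warns(UserWarning):
            mask = remove_background(cube, threshold_deg=0.0, clean=False)
        assert mask.tissue.mean() < 0.05


class TestReduceCube:
    def _native(self, rows=8, cols=6):
        wav = np.arange(400.0, 1000.1, 2.9)
        rng = np.random.default_rng(0)
        data = rng.uniform(0.1, 0.9, (rows, cols, wav.size))
        return HyperCube(data, WavelengthGrid(wav), stage="normalized")

    def test_native_grid_reduces_to_61_bands(self):
        red = reduce_cube(self._native())
        assert red.data.shape == (4, 3, 61)
        assert len(red.grid) == 61
        assert red.grid.lo == 450.0 and red.grid.hi == 750.0

    def test_spatial_binning_halves_dimensions(self):
        red = reduce_cube(self._native(rows=12, cols=10))
        assert red.data.shape[:2] == (6, 5)

    def test_constant_cube_stays_constant(self):
        wav = np.arange(400.0, 1000.1, 2.9)
        cube = HyperCube(np.full((4, 4, wav.size), 0.37),
                         WavelengthGrid(wav), stage="normalized")
        red = reduce_cube(cube)
        np.testing.assert_allclose(red.data, 0.37)

    def test_spectrally_idempotent_on_reduced_grid(self):
        cube = HyperCube(np.random.default_rng(1).uniform(
            0, 1, (4, 4, 61)), default_grid(), stage="normalized")
        red = reduce_cube(cube, spatial_bin=1)
        np.testing.assert_array_equal(red.data, cube.data)

    def test_insufficient_coverage_rejected(self):
        cube = HyperCube(np.ones((4, 4, 20)),
                         WavelengthGrid(np.linspace(500, 700, 20)))
        with pytest.raises(ValueError):
            reduce_cube(cube)


class TestErythemaIndex:
    def test_flat_spectrum_gives_unity(self):
        cube = HyperCube(np.full((3, 3, 61), 0.4), default_grid(),
                         stage="reduced")
        np.testing.assert_allclose(erythema_index(cube), 1.0)

    def test_scaling_invariance(self, rng):
        data = rng.uniform(0.1, 0.9, (4, 4, 61))
        cube = HyperCube(data, default_grid(), stage="reduced")
        cube2 = HyperCube(3.0 * data, default_grid(), stage="reduced")
        np.testing.assert_allclose(erythema_index(cube2),
                                   erythema_index(cube))

    def test_high_blood_pixel_has_larger_index(self, lib, grid):
        from spectromics.optics import simulate_spectrum
        from spectromics.params import SkinTissueParams
        lo = simulate_spectrum(SkinTissueParams(fHb=0.005), lib, grid)
        hi = simulate_spectrum(SkinTissueParams(fHb=0.05), lib, grid)
        data = np.stack([np.tile(lo, (2, 1)), np.tile(hi, (2, 1))])
        cube = HyperCube(data, grid, stage="reduced")
        ei = erythema_index(cube)
        assert np.all(ei[1] > ei[0])


class TestEIDisplay:
    def test_constant_map_stays_constant(self):
        out = prepare_ei_display(np.full((16, 16), 1.3))
        assert np.all(out == out.flat[0])

    def test_outlier_removed_and_range_normalized(self, rng):
        m = rng.uniform(1.0, 1.2, (24, 24))
        m[5, 5] = 50.0
        out = prepare_ei_display(m)
        assert out.min() >= 0.0 and out.max() <= 1.0
        # the single-pixel spike is flattened by the median filter: the
        # center pixel no longer towers over its neighborhood
        neigh = out[4:7, 4:7]
        assert out[5, 5] <= neigh.max()
        assert out[5, 5] - np.median(neigh) < 0.5
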