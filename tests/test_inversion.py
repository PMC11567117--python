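"""Bounded inverse fitting of the skin model."""
import numpy as np
import pytest

from spectromics.inversion import (
    default_bounds,
    default_cube_bounds,
    fit_cube,
    fit_spectrum,
)
from spectromics.lut import simulate_spectrum_lut
from spectromics.optics import simulate_spectrum
from spectromics.params import PARAM_NAMES, SkinTissueParams


class TestFitSpectrum:
    def test_fixed_point_recovery(self, lib, grid):
        """A noise-free model spectrum with the truth as initial guess is
        a fixed point: parameters stay put and the residual vanishes."""
        p = SkinTissueParams(fm=0.02, fHb=0.015, fHbO2=0.012, a=2.0, b=1.2)
        y = simulate_spectrum(p, lib, grid)
        b = default_bounds()
        init = {n: getattr(p, n) for n in PARAM_NAMES}
        b = b.replace(**{n: (b.lower[n], b.upper[n], init[n])
                         for n in PARAM_NAMES if b.lower[n] < b.upper[n]})
        fr = fit_spectrum(y, grid, lib, b)
        assert fr.residual < 1e-10
        assert fr.thb == pytest.approx(2.7, abs=0.05)

    def test_default_init_recovery(self, lut, lib, grid):
        """Default initialization recovers the main parameters of a clean
        spectrum: 10% relative on the hemoglobin fractions and melanin,
        2 points on THB/StO2."""
        p = SkinTissueParams(fm=0.025, fHb=0.016, fHbO2=0.013, a=2.2, b=1.0)
        y = simulate_spectrum_lut(p, lut, lib, grid)
        fr = fit_spectrum(y, grid, lib, default_cube_bounds(),
                          forward="lut", lut=lut)
        assert fr.params.fHb == pytest.approx(p.fHb, rel=0.10)
        assert fr.params.fHbO2 == pytest.approx(p.fHbO2, rel=0.10)
        assert fr.params.fm == pytest.approx(p.fm, rel=0.10)
        assert fr.thb == pytest.approx(100 * (p.fHb + p.fHbO2), abs=2.0)
        assert fr.sto2 == pytest.approx(
            100 * p.fHbO2 / (p.fHb + p.fHbO2), abs=2.0)

    def test_out_of_bounds_target_pins_at_bound(self, lut, lib, grid):
        """A spectrum generated beyond the fHb upper bound saturates the
        fitted fHb at that bound and flags it."""
        target = SkinTissueParams(fHb=0.08, fHbO2=0.005, fm=0.02)
        y = simulate_spectrum_lut(target, lut, lib, grid)
        b = default_cube_bounds().replace(fHb=(0.0, 0.03, 0.01))
        fr = fit_spectrum(y, grid, lib, b, forward="lut", lut=lut)
        assert fr.at_bound["fHb"]
        assert fr.params.fHb == pytest.approx(0.03, abs=1e-4)

    def test_residual_reproducible_from_params(self, lut, lib, grid, rng):
        """Re-simulating the fitted parameters reproduces the stored
        residual bitwise."""
        p = SkinTissueParams(fHb=0.02, fHbO2=0.015)
        y = np.clip(simulate_spectrum_lut(p, lut, lib, grid)
                    * (1 + 0.01 * rng.standard_normal(61)), 0, 1.5)
        fr = fit_spectrum(y, grid, lib, default_cube_bounds(),
                          forward="lut", lut=lut)
        again = simulate_spectrum_lut(fr.params, lut, lib, grid)
        assert float(np.sum((again - y) ** 2)) == fr.residual

    def test_bounds_respected(self, lut, lib, grid, rng):
        b = default_cube_bounds()
        lo, up, _ = b.arrays()
        for _ in range(5):
            p = SkinTissueParams(fHb=rng.uniform(0.003, 0.06),
                                 fHbO2=rng.uniform(0.003, 0.06),
                                 fm=rng.uniform(0.005, 0.06),
                                 a=rng.uniform(1.0, 4.0),
                                 b=rng.uniform(0.3, 2.0))
            y = np.clip(simulate_spectrum_lut(p, lut, lib, grid)
                        * (1 + 0.02 * rng.standard_normal(61)), 0, 1.5)
            fr = fit_spectrum(y, grid, lib, b, forward="lut", lut=lut)
            x = fr.params.as_array()
            assert np.all(x >= lo - 1e-12) and np.all(x <= up + 1e-12)

    def test_bad_inputs_rejected(self, lib, grid):
        with pytest.raises(ValueError):
            fit_spectrum(np.full(61, np.nan), grid, lib)
        with pytest.raises(ValueError):
            fit_spectrum(np.full(60, 0.5), grid, lib)
        with pytest.raises(ValueError):
            fit_spectrum(np.full(61, -0.2), grid, lib)

    def test_recovery_under_noise(self, lut, lib, grid):
        """100 physiologic parameter draws with 1% multiplicative spectral
        noise: median absolute recovery error within 0.5 THB points and
        5 StO2 points."""
        rng = np.random.default_rng(202)
        errs_thb = []
        errs_sto2 = []
        for _ in range(100):
            thb = rng.uniform(1.5, 8.0) / 100
            sto2 = rng.uniform(0.2, 0.65)
            p = SkinTissueParams(fm=rng.uniform(0.01, 0.035),
                                 fHb=thb * (1 - sto2), fHbO2=thb * sto2,
                                 a=rng.uniform(1.5, 2.8),
                                 b=rng.uniform(0.7, 1.7))
            y = np.clip(simulate_spectrum_lut(p, lut, lib, grid)
                        * (1 + 0.01 * rng.standard_normal(61)), 0, 1.5)
            fr = fit_spectrum(y, grid, lib, default_cube_bounds(),
                              forward="lut", lut=lut)
            errs_thb.append(abs(fr.thb - 100 * thb))
            errs_sto2.append(abs(fr.sto2 - 100 * sto2))
        assert np.median(errs_thb) <= 0.5
        assert np.median(errs_sto2) <= 5.0


class TestFitCube:
    def _phantom(self, lut, lib, grid, rng, two_region=False):
        rows, cols = 16, 20
        p_h = SkinTissueParams(fm=0.02, fHb=0.016, fHbO2=0.011, a=2.0, b=1.2)
        cube = np.empty((rows, cols, 61))
        cube[:] = simulate_spectrum_lut(p_h, lut, lib, grid)
        region = np.zeros((rows, cols), bool)
        if two_region:
            region[4:12, 6:14] = True
            p_t = SkinTissueParams(fm=0.02, fHb=0.025, fHbO2=0.025,
                                   a=2.4, b=0.9)
            cube[region] = simulate_spectrum_lut(p_t, lut, lib, grid)
        return cube, region

    def test_constant_phantom_gives_constant_maps(self, lut, lib, grid, rng):
        cube, _ = self._phantom(lut, lib, grid, rng)
        mask = np.ones(cube.shape[:2], bool)
        maps = fit_cube(cube, mask, grid, lib, lut=lut)
        thb = 100 * (maps.map("fHb") + maps.map("fHbO2"))
        assert np.nanstd(thb) < 0.02
        assert np.nanmean(thb) == pytest.approx(2.7, abs=0.1)

    def test_two_region_phantom_separates(self, lut, lib, grid, rng):
        cube, region = self._phantom(lut, lib, grid, rng, two_region=True)
        cube = np.clip(cube * (1 + 0.005 * rng.standard_normal(cube.shape)),
                       0, 1.5)
        mask = np.ones(cube.shape[:2], bool)
        maps = fit_cube(cube, mask, grid, lib, lut=lut)
        thb = 100 * (maps.map("fHb") + maps.map("fHbO2"))
        assert np.nanmean(thb[region]) > np.nanmean(thb[~region]) + 1.0

    def test_masked_pixels_never_fitted(self, lut, lib, grid, rng):
        cube, _ = self._phantom(lut, lib, grid, rng)
        mask = np.zeros(cube.shape[:2], bool)
        mask[2:6, 3:9] = True
        maps = fit_cube(cube, mask, grid, lib, lut=lut)
        assert np.all(np.isnan(maps.map("fHb")[~mask]))
        assert np.all(np.isfinite(maps.map("fHb")[mask]))
        assert np.array_equal(maps.valid, mask)

    def test_empty_mask_rejected(self, lut, lib, grid, rng):
        cube, _ = self._phantom(lut, lib, grid, rng)
        with pytest.raises(ValueError):
            fit_cube(cube, np.zeros(cube.shape[:2], bool), grid, lib, lut=lut)

    def test_exact_strategy_on_tiny_cube(self, lut, lib, grid):
        p = SkinTissueParams(fm=0.02, fHb=0.016, fHbO2=0.011, a=2.0, b=1.2)
        cube = np.empty((2, 2, 61))
        cube[:] = simulate_spectrum(p, lib, grid)
        mask = np.ones((2, 2), bool)
        maps = fit_cube(cube, mask, grid, lib, strategy="exact",
                        bounds=default_cube_bounds())
        thb = 100 * (maps.map("fHb") + maps.map("fHbO2"))
        assert np.nanmean(thb) == pytest.approx(2.7, abs=0.2)
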