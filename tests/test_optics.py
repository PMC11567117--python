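"""Forward model: chromophore mixing, scattering law, adding-doubling."""
import numpy as np
import pytest

from spectromics.adding_doubling import (
    ConfigurationError,
    adding_doubling_reflectance,
    adding_doubling_rt,
)
from spectromics.chromophores import CoverageError, load_default_library
from spectromics.grids import WavelengthGrid, default_grid
from spectromics.optics import (
    dermis_absorption,
    epidermis_absorption,
    reduced_scattering,
    simulate_spectrum,
)
from spectromics.params import LayerOpticalProperties, SkinTissueParams


class TestChromophoreLibrary:
    def test_covers_default_grid_and_positive(self, lib, grid):
        for name in ("melanin", "hb", "hbo2", "bilirubin", "baseline"):
            v = lib.sample(name, grid)
            assert v.shape == (61,)
            assert np.all(v >= 0)

    def test_hemoglobin_isosbestic_crossing(self, lib, grid):
        """Deoxy and oxy curves must cross at least once in 500-600 nm."""
        w = grid.wavelengths
        d = lib.sample("hb", grid) - lib.sample("hbo2", grid)
        sel = (w >= 500) & (w <= 600)
        assert np.sum(np.diff(np.sign(d[sel])) != 0) >= 1

    def test_out_of_coverage_grid_raises(self, lib):
        bad = WavelengthGrid(np.arange(300.0, 500.0, 5.0))
        with pytest.raises(CoverageError):
            lib.sample("hb", bad)


class TestAbsorptionMixing:
    def test_no_melanin_gives_baseline(self, lib, grid):
        p = SkinTissueParams(fm=0.0)
        assert np.array_equal(epidermis_absorption(p, lib, grid),
                              lib.sample("baseline", grid))

    def test_epidermis_hand_sum_at_500nm(self, lib, grid):
        fm = 0.02
        p = SkinTissueParams(fm=fm)
        mua = epidermis_absorption(p, lib, grid)
        i = int(np.flatnonzero(grid.wavelengths == 500.0)[0])
        expected = fm * lib.sample("melanin", grid)[i] \
            + lib.sample("baseline", grid)[i]
        assert mua[i] == pytest.approx(expected, rel=1e-12)
        assert np.all(mua >= lib.sample("baseline", grid))

    def test_bloodless_dermis_is_baseline(self, lib, grid):
        p = SkinTissueParams(fHb=0, fHbO2=0, fbrub=0, fCO=0, fCOO2=0)
        assert np.array_equal(dermis_absorption(p, lib, grid),
                              lib.sample("baseline", grid))

    def test_dermis_hand_sum_at_550nm(self, lib, grid):
        p = SkinTissueParams(fHb=0.01, fHbO2=0.01, fbrub=0, fCO=0, fCOO2=0)
        mua = dermis_absorption(p, lib, grid)
        i = int(np.flatnonzero(grid.wavelengths == 550.0)[0])
        expected = 0.01 * lib.sample("hb", grid)[i] \
            + 0.01 * lib.sample("hbo2", grid)[i] \
            + lib.sample("baseline", grid)[i]
        assert mua[i] == pytest.approx(expected, rel=1e-12)

    def test_dermis_linearity_without_baseline(self, lib, grid):
        base = lib.sample("baseline", grid)
        p1 = SkinTissueParams(fHb=0.01, fHbO2=0.02, fbrub=1e-5,
                              fCO=2e-5, fCOO2=1e-5)
        p2 = SkinTissueParams(fHb=0.02, fHbO2=0.04, fbrub=2e-5,
                              fCO=4e-5, fCOO2=2e-5)
        d1 = dermis_absorption(p1, lib, grid) - base
        d2 = dermis_absorption(p2, lib, grid) - base
        np.testing.assert_allclose(d2, 2 * d1, rtol=1e-12)


class TestReducedScattering:
    def test_amplitude_at_500nm(self):
        g500 = WavelengthGrid(np.array([450.0, 500.0, 550.0]))
        for b, fray in ((0.5, 0.1), (2.0, 0.7)):
            p = SkinTissueParams(a=1.7, b=b, fRay=fray)
            assert reduced_scattering(p, g500)[1] == pytest.approx(1.7)

    def test_flat_when_b_zero_no_rayleigh(self, grid):
        p = SkinTissueParams(a=2.5, b=0.0, fRay=0.0)
        np.testing.assert_allclose(reduced_scattering(p, grid), 2.5)

    def test_pure_rayleigh_at_1000nm(self):
        g = WavelengthGrid(np.array([500.0, 1000.0]))
        p = SkinTissueParams(a=2.0, fRay=1.0)
        assert reduced_scattering(p, g)[1] == pytest.approx(2.0 / 16.0)

    def test_monotone_nonincreasing_for_positive_b(self, grid):
        p = SkinTissueParams(a=2.0, b=1.3, fRay=0.3)
        assert np.all(np.diff(reduced_scattering(p, grid)) <= 0)


class TestAddingDoubling:
    @pytest.mark.parametrize("order", [8, 16, 32])
    @pytest.mark.parametrize("g", [0.0, 0.9])
    def test_conservative_slab_energy(self, order, g):
        lay = LayerOpticalProperties(mua=np.array([0.0]),
                                     musp=np.array([1.0]),
                                     g=g, n=1.0, d=1.0)
        R, T = adding_doubling_rt([lay], order, 1.0)
        assert R[0] + T[0] == pytest.approx(1.0, abs=1e-6)

    def test_pure_absorber_reflects_nothing(self):
        lay = LayerOpticalProperties(mua=np.array([1.0]),
                                     musp=np.array([1e-12]),
                                     g=0.0, n=1.0, d=50.0)
        R = adding_doubling_reflectance([lay], 16, 1.0)
        assert R[0] == pytest.approx(0.0, abs=1e-9)

    def test_low_order_rejected(self):
        lay = LayerOpticalProperties(mua=np.array([0.1]),
                                     musp=np.array([1.0]), d=1.0)
        with pytest.raises(ConfigurationError):
            adding_doubling_rt([lay], 3, 1.0)

    def test_deterministic(self):
        lay = LayerOpticalProperties(mua=np.array([0.1, 0.3]),
                                     musp=np.array([2.0, 1.5]),
                                     g=0.9, n=1.4, d=20.0)
        r1 = adding_doubling_reflectance([lay])
        r2 = adding_doubling_reflectance([lay])
        assert np.array_equal(r1, r2)

    def test_monotone_in_absorption_and_scattering(self):
        muas = np.linspace(0.01, 2.0, 8)
        lay = LayerOpticalProperties(mua=muas, musp=np.full(8, 2.0),
                                     g=0.9, n=1.4, d=20.0)
        R = adding_doubling_reflectance([lay])
        assert np.all(np.diff(R) < 0)
        musps = np.linspace(0.5, 5.0, 8)
        lay = LayerOpticalProperties(mua=np.full(8, 0.1), musp=musps,
                                     g=0.9, n=1.4, d=20.0)
        R = adding_doubling_reflectance([lay])
        assert np.all(np.diff(R) > 0)


class TestSimulateSpectrum:
    def test_output_range_and_shape(self, lib, grid):
        r = simulate_spectrum(SkinTissueParams(), lib, grid)
        assert r.shape == (61,)
        assert np.all((r >= 0) & (r <= 1))

    def test_more_blood_darkens_green_band(self, lib, grid):
        w = grid.wavelengths
        band = (w >= 500) & (w <= 600)
        lo = simulate_spectrum(SkinTissueParams(fHb=0.01), lib, grid)
        hi = simulate_spectrum(SkinTissueParams(fHb=0.05), lib, grid)
        assert hi[band].mean() < lo[band].mean()

    def test_thin_epidermis_converges_to_pure_dermis(self, lib, grid):
        p = SkinTissueParams(fm=0.05, de=1e-4)
        thin = simulate_spectrum(p, lib, grid)
        # pure dermis: epidermis with no melanin and negligible thickness
        pure = simulate_spectrum(p.replace(fm=0.0), lib, grid)
        assert np.max(np.abs(thin - pure)) < 0.005

    def test_bitwise_deterministic(self, lib, grid):
        p = SkinTissueParams()
        assert np.array_equal(simulate_spectrum(p, lib, grid),
                              simulate_spectrum(p, lib, grid))


class TestWavelengthGrid:
    def test_default_grid_is_450_to_750_in_5nm(self, grid):
        assert len(grid) == 61
        assert grid.lo == 450.0 and grid.hi == 750.0
        assert np.all(np.diff(grid.wavelengths) == 5.0)

    def test_non_increasing_grid_rejected(self):
        with pytest.raises(ValueError):
            WavelengthGrid(np.array([500.0, 500.0, 510.0]))
        with pytest.raises(ValueError):
            WavelengthGrid(np.array([510.0, 500.0]))


class TestParamValidation:
    @pytest.mark.parametrize("kw", [dict(fm=-0.1), dict(fHb=1.2),
                                    dict(a=0.0), dict(de=0.0)])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            SkinTissueParams(**kw)

    def test_layer_invariants(self):
        with pytest.raises(ValueError):
            LayerOpticalProperties(mua=np.array([-0.1]),
                                   musp=np.array([1.0]), d=1.0)
        with pytest.raises(ValueError):
            LayerOpticalProperties(mua=np.array([0.1]),
                                   musp=np.array([1.0]), g=1.0, d=1.0)
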