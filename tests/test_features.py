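"""Derived maps, first-order and co-occurrence features, table layout."""
import numpy as np
import pytest

from spectromics.features import (
    FeatureConfig,
    feature_descriptor,
    feature_index,
    first_order_features,
    gaussian_smooth_maps,
    glcm_features,
    region_features,
    sto2_map,
    thb_map,
)
from spectromics.inversion import ParameterMaps
from spectromics.params import PARAM_NAMES


def _maps(shape=(6, 8), **overrides):
    params = {}
    defaults = dict(fm=0.02, fHb=0.015, fHbO2=0.012, fbrub=0.0, fCO=0.0,
                    fCOO2=0.0, a=2.0, b=1.2, fRay=0.2, de=0.06, dd=20.0)
    defaults.update(overrides)
    for n in PARAM_NAMES:
        params[n] = np.full(shape, float(defaults[n]))
    return ParameterMaps(params=params, residual=np.zeros(shape),
                         valid=np.ones(shape, bool),
                         converged=np.ones(shape, bool))


class TestDerivedMaps:
    @pytest.mark.parametrize("fhb,fhbo2,expected", [
        (0.0, 0.0, 0.0),
        (0.01, 0.02, 3.0),
        (0.015, 0.012, 2.7),
    ])
    def test_thb_arithmetic(self, fhb, fhbo2, expected):
        m = _maps(fHb=fhb, fHbO2=fhbo2)
        np.testing.assert_allclose(thb_map(m), expected)

    @pytest.mark.parametrize("fhb,fhbo2,expected", [
        (0.02, 0.02, 50.0),
        (0.0, 0.03, 100.0),
        (0.02, 0.01, 100.0 / 3.0),
    ])
    def test_sto2_arithmetic(self, fhb, fhbo2, expected):
        m = _maps(fHb=fhb, fHbO2=fhbo2)
        np.testing.assert_allclose(sto2_map(m), expected)

    def test_sto2_masked_not_thrown_at_zero_blood(self):
        m = _maps(fHb=0.0, fHbO2=0.0)
        assert np.all(np.isnan(sto2_map(m)))


class TestFirstOrder:
    def test_constant_region_degenerate_conventions(self):
        vals = np.full((4, 4), 3.3)
        mask = np.ones((4, 4), bool)
        mean, sd, skew, kurt, ent, en = first_order_features(vals, mask)
        assert (mean, sd, skew, kurt) == (3.3, 0.0, 0.0, 0.0)
        assert ent == 0.0 and en == 1.0

    def test_two_level_histogram_closed_form(self):
        vals = np.array([[0.0, 1.0]] * 4)
        mask = np.ones((4, 2), bool)
        *_, ent, en = first_order_features(vals, mask, FeatureConfig(ng=8))
        assert ent == pytest.approx(1.0)
        assert en == pytest.approx(0.5)

    def test_four_pixel_hand_case(self):
        vals = np.array([[1.0, 2.0], [3.0, 4.0]])
        mask = np.ones((2, 2), bool)
        mean, sd, skew, kurt, ent, en = first_order_features(
            vals, mask, FeatureConfig(ng=4))
        assert mean == pytest.approx(2.5)
        assert sd == pytest.approx(np.std([1, 2, 3, 4], ddof=1))
        assert ent == pytest.approx(2.0)
        assert en == pytest.approx(0.25)

    def test_pixel_order_irrelevant(self, rng):
        vals = rng.uniform(0, 1, (5, 7))
        mask = np.ones((5, 7), bool)
        a = first_order_features(vals, mask)
        perm = vals.flatten()
        rng.shuffle(perm)
        b = first_order_features(perm.reshape(5, 7), mask)
        np.testing.assert_allclose(a, b)

    def test_entropy_and_energy_bounds(self, rng):
        cfg = FeatureConfig(ng=16)
        for _ in range(10):
            vals = rng.standard_normal((8, 8))
            mask = rng.uniform(size=(8, 8)) > 0.3
            if mask.sum() < 2:
                continue
            *_, ent, en = first_order_features(vals, mask, cfg)
            assert 0.0 <= ent <= np.log2(cfg.ng)
            assert 1.0 / cfg.ng <= en <= 1.0

    def test_tiny_region_rejected(self):
        with pytest.raises(ValueError):
            first_order_features(np.ones((3, 3)), np.eye(3, dtype=bool) * 0)


class TestGLCM:
    def test_constant_region_diagonal_matrix(self):
        c, h = glcm_features(np.full((5, 5), 2.0), np.ones((5, 5), bool))
        assert c == 0.0 and h == 1.0

    @pytest.mark.parametrize("ng", [4, 8, 32])
    def test_checkerboard_closed_form(self, ng):
        """2x2 checkerboard of extreme levels, horizontal offset:
        contrast (Ng-1)^2 and homogeneity 1/Ng from the hand-built GLCM."""
        board = np.array([[0.0, 1.0], [1.0, 0.0]])
        c, h = glcm_features(board, np.ones((2, 2), bool),
                             FeatureConfig(ng=ng, angles=(0,)))
        assert c == pytest.approx((ng - 1) ** 2)
        assert h == pytest.approx(1.0 / ng)

    def test_stripes_less_homogeneous_than_constant(self):
        stripes = np.tile([0.0, 1.0], (6, 3))
        mask = np.ones((6, 6), bool)
        _, h_const = glcm_features(np.ones((6, 6)), mask)
        _, h_stripes = glcm_features(stripes, mask)
        assert h_stripes < h_const

    def test_bounds(self, rng):
        cfg = FeatureConfig(ng=8)
        vals = rng.uniform(0, 1, (10, 10))
        mask = rng.uniform(size=(10, 10)) > 0.2
        c, h = glcm_features(vals, mask, cfg)
        assert 0.0 <= c <= (cfg.ng - 1) ** 2
        assert 0.0 < h <= 1.0

    def test_no_valid_pairs_rejected(self):
        mask = np.zeros((5, 5), bool)
        mask[0, 0] = True
        mask[4, 4] = True  # no pair at offset 1 in any direction
        with pytest.raises(ValueError):
            glcm_features(np.ones((5, 5)), mask, FeatureConfig(delta=1))


class TestLayout:
    def test_printed_anchor_columns(self):
        assert feature_index("mean", "StO2") == 5
        assert feature_index("skewness", "StO2") == 25
        assert feature_index("entropy", "fm") == 41
        assert feature_index("homogeneity", "THB") == 74
        assert feature_index("sd", "b") == 20
        assert feature_index("skewness", "a") == 29
        assert feature_index("homogeneity", "fHbO2") == 73

    def test_bijection(self):
        seen = set()
        for i in range(1, 81):
            stat, param = feature_descriptor(i)
            assert feature_index(stat, param) == i
            seen.add((stat, param))
        assert len(seen) == 80

    def test_region_vector_has_80_entries(self, rng):
        m = _maps()
        for n in ("fm", "fHb", "fHbO2", "a", "b"):
            m.params[n] += 0.001 * rng.standard_normal(m.shape)
        vec = region_features(m, np.ones(m.shape, bool))
        assert vec.shape == (80,)
        assert np.all(np.isfinite(vec))


class TestSmoothing:
    def test_sigma_zero_is_bitwise_identity(self, rng):
        m = _maps()
        m.params["fHb"] += 0.001 * rng.standard_normal(m.shape)
        sm = gaussian_smooth_maps(m, 0.0)
        for n in PARAM_NAMES:
            assert np.array_equal(sm.map(n), m.map(n))

    def test_constant_map_unchanged(self):
        m = _maps()
        sm = gaussian_smooth_maps(m, 3.0)
        for n in PARAM_NAMES:
            np.testing.assert_allclose(sm.map(n), m.map(n), rtol=1e-12)

    def test_spike_spread_and_mean_preserved(self):
        m = _maps(shape=(21, 21))
        spike = np.zeros((21, 21))
        spike[10, 10] = 1.0
        m.params["fHb"] = spike
        sm = gaussian_smooth_maps(m, 2.0)
        out = sm.map("fHb")
        assert out[10, 10] < 1.0
        assert out.sum() == pytest.approx(1.0, rel=0.01)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth_maps(_maps(), -1.0)
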