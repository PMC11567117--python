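"""Precomputed reflectance table for fast forward evaluation.

Reflectance of the two-layer stack depends on wavelength only through
three scalars -- epidermal absorption, dermal absorption and the shared
reduced scattering -- once anisotropy, refractive index and the layer
thicknesses are fixed.  A dense 3-D table over (log mu_a,e, log mu_a,d,
mu_s') therefore replaces per-wavelength adding-doubling with a trilinear
interpolation, which makes per-pixel cube fitting tractable on one CPU.
The table is validated against the exact solver in the test suite.
"""
from __future__ import annotations

import numpy as np

from .adding_doubling import (
    _combine,
    _fresnel_inside,
    _quadrature,
    _slab_rt,
)
from .chromophores import ChromophoreLibrary, load_default_library
from .grids import WavelengthGrid, default_grid
from .params import (
    DD_SEMI_INFINITE,
    G_HENYEY_GREENSTEIN,
    N_AMBIENT,
    N_TISSUE,
    SkinTissueParams,
)

__all__ = ["ReflectanceLUT", "build_default_lut", "simulate_spectrum_lut"]

_LUT_CACHE: dict = {}


class ReflectanceLUT:
    """Trilinear reflectance table over layer optical properties.

    Axes: log mu_a,epidermis, log mu_a,dermis (both 1/mm) and the shared
    reduced scattering mu_s' (1/mm).  Epidermis thickness ``de`` and the
    (semi-infinite) dermis thickness are frozen into the table.
    """

    def __init__(self, mua_e_axis, mua_d_axis, musp_axis, de,
                 dd=DD_SEMI_INFINITE, g=G_HENYEY_GREENSTEIN,
                 n=N_TISSUE, n_ambient=N_AMBIENT, quadrature_order=16):
        self.mua_e_axis = np.asarray(mua_e_axis, float)
        self.mua_d_axis = np.asarray(mua_d_axis, float)
        self.musp_axis = np.asarray(musp_axis, float)
        self.de = float(de)
        self.dd = float(dd)
        self.g = float(g)
        self.n = float(n)
        self.n_ambient = float(n_ambient)
        self.order = int(quadrature_order)
        self._log_e = np.log(self.mua_e_axis)
        self._log_d = np.log(self.mua_d_axis)
        self.table = self._build()

    def _build(self):
        n_rel = round(self.n / self.n_ambient, 12)
        mu, _w = _quadrature(self.order, n_rel)
        M = mu.size
        ne, nd, ns = (self.mua_e_axis.size, self.mua_d_axis.size,
                      self.musp_axis.size)

        # layer matrices on the two marginal grids
        mue = np.repeat(self.mua_e_axis, ns)
        muse = np.tile(self.musp_axis, ne) / (1.0 - self.g)
        Re, Te = _slab_rt(mue, muse, self.g, self.de, self.order, n_rel)
        Re = Re.reshape(ne, ns, M, M)
        Te = Te.reshape(ne, ns, M, M)

        mud = np.repeat(self.mua_d_axis, ns)
        musd = np.tile(self.musp_axis, nd) / (1.0 - self.g)
        Rd, Td = _slab_rt(mud, musd, self.g, self.dd, self.order, n_rel)
        Rd = Rd.reshape(nd, ns, M, M)
        Td = Td.reshape(nd, ns, M, M)

        rF = _fresnel_inside(mu, n_rel) if n_rel > 1 else np.zeros(M)
        r_spec = ((n_rel - 1) / (n_rel + 1)) ** 2 if n_rel > 1 else 0.0
        Rb = np.diag(rF)
        eye = np.eye(M)
        beam = M - 1

        out = np.empty((ne, nd, ns))
        for i in range(ne):  # chunk over the epidermis axis to bound memory
            R1 = Re[i][None, :, :, :]          # (1, ns, M, M)
            T1 = Te[i][None, :, :, :]
            R, T = _combine(np.broadcast_to(R1, Rd.shape).copy(),
                            np.broadcast_to(T1, Td.shape).copy(), Rd, Td)
            if n_rel > 1:
                R, T = _combine(R, T, np.broadcast_to(Rb, R.shape).copy(),
                                np.diag(1.0 - rF) + np.zeros_like(R))
                d0 = np.zeros(M)
                d0[beam] = 1.0 - r_spec
                u0 = np.einsum("...ij,j->...i", R, d0)
                u = np.linalg.solve(eye - R @ Rb, u0[..., None])[..., 0]
                out[i] = np.einsum("i,...i->...", 1.0 - rF, u)
            else:
                out[i] = R[..., :, beam].sum(axis=-1)
        return out

    def _locate(self, v, axis, log):
        x0, x1 = axis[0], axis[-1]
        n = axis.size
        if log:
            x = np.log(np.clip(v, np.exp(x0), np.exp(x1)))
        else:
            x = np.clip(v, x0, x1)
        pos = (x - x0) * ((n - 1) / (x1 - x0))
        i = np.clip(pos.astype(np.intp), 0, n - 2)
        return i, pos - i

    def evaluate(self, mua_e, mua_d, musp):
        """Trilinear interpolation; inputs broadcast elementwise.

        All three axes are uniform in their transformed coordinate
        (log for the absorption axes), so cell location is arithmetic.
        """
        ix, fx = self._locate(np.asarray(mua_e, float), self._log_e, True)
        iy, fy = self._locate(np.asarray(mua_d, float), self._log_d, True)
        iz, fz = self._locate(np.asarray(musp, float), self.musp_axis, False)
        t = self.table
        nd, ns = t.shape[1], t.shape[2]
        flat = t.ravel()
        base = (ix * nd + iy) * ns + iz
        c00 = flat[base] * (1 - fz) + flat[base + 1] * fz
        c01 = flat[base + ns] * (1 - fz) + flat[base + ns + 1] * fz
        c10 = flat[base + nd * ns] * (1 - fz) + flat[base + nd * ns + 1] * fz
        c11 = (flat[base + nd * ns + ns] * (1 - fz)
               + flat[base + nd * ns + ns + 1] * fz)
        c0 = c00 * (1 - fy) + c01 * fy
        c1 = c10 * (1 - fy) + c11 * fy
        return c0 * (1 - fx) + c1 * fx


def build_default_lut(de: float = 0.06, quadrature_order: int = 16,
                      cached: bool = True) -> ReflectanceLUT:
    """Default table spanning the physiologic fit bounds.

    Absorption axes are log-spaced from the bloodless baseline up to fully
    saturated chromophore loading; scattering covers a in [0.5, 5] across
    the 450-750 nm power laws.
    """
    key = (round(de, 6), quadrature_order)
    if cached and key in _LUT_CACHE:
        return _LUT_CACHE[key]
    lut = ReflectanceLUT(
        mua_e_axis=np.geomspace(2e-3, 12.0, 40),
        mua_d_axis=np.geomspace(2e-3, 18.0, 64),
        musp_axis=np.linspace(0.15, 8.5, 96),
        de=de,
        quadrature_order=quadrature_order,
    )
    if cached:
        _LUT_CACHE[key] = lut
    return lut


class _LibrarySamples:
    """Chromophore tables pre-sampled on a fixed grid (vectorized mixing)."""

    def __init__(self, lib: ChromophoreLibrary, grid: WavelengthGrid):
        self.grid = grid
        self.mel = lib.sample("melanin", grid)
        self.hb = lib.sample("hb", grid)
        self.hbo2 = lib.sample("hbo2", grid)
        self.brub = lib.sample("bilirubin", grid)
        self.cco_r = lib.sample("cco_reduced", grid)
        self.cco_o = lib.sample("cco_oxidized", grid)
        self.base = lib.sample("baseline", grid)
        self.lam = grid.wavelengths / 500.0
        self.lam_m4 = self.lam**-4.0
        self.log_lam = np.log(self.lam)

    def optical_properties(self, theta):
        """Map parameter matrix (N, 11) -> (mua_e, mua_d, musp), each (N, L)."""
        th = np.atleast_2d(theta)
        fm, fHb, fHbO2, fbrub, fCO, fCOO2, a, b, fRay = th[:, :9].T
        mua_e = fm[:, None] * self.mel + self.base
        mua_d = (fHb[:, None] * self.hb + fHbO2[:, None] * self.hbo2
                 + fbrub[:, None] * self.brub + fCO[:, None] * self.cco_r
                 + fCOO2[:, None] * self.cco_o + self.base)
        mie = np.exp(-b[:, None] * self.log_lam)
        musp = a[:, None] * (fRay[:, None] * self.lam_m4
                             + (1.0 - fRay)[:, None] * mie)
        return mua_e, mua_d, musp


def simulate_spectrum_lut(p: SkinTissueParams, lut: ReflectanceLUT,
                          lib: ChromophoreLibrary | None = None,
                          grid: WavelengthGrid | None = None) -> np.ndarray:
    """Reflectance spectrum through the interpolated forward model."""
    lib = lib or load_default_library()
    grid = grid or default_grid()
    samples = _LibrarySamples(lib, grid)
    mua_e, mua_d, musp = samples.optical_properties(p.as_array()[None, :])
    return lut.evaluate(mua_e, mua_d, musp)[0]
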