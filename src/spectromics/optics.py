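"""Forward reflectance model of two-layer murine skin.

Chromophore mixing rules give the absorption spectra of the epidermis
(melanin over a bloodless baseline) and dermis (hemoglobins, bilirubin,
cytochrome-c oxidase over the same baseline); a shared three-term power
law gives the reduced scattering.  The adding-doubling solver turns the
two layer stacks into a total diffuse reflectance spectrum.
"""
from __future__ import annotations

import numpy as np

from .adding_doubling import adding_doubling_rt
from .chromophores import ChromophoreLibrary, load_default_library
from .grids import WavelengthGrid, default_grid
from .params import (
    G_HENYEY_GREENSTEIN,
    LayerOpticalProperties,
    N_AMBIENT,
    N_TISSUE,
    SkinTissueParams,
)

__all__ = [
    "epidermis_absorption",
    "dermis_absorption",
    "reduced_scattering",
    "build_layers",
    "simulate_spectrum",
]


def epidermis_absorption(p: SkinTissueParams, lib: ChromophoreLibrary,
                         grid: WavelengthGrid) -> np.ndarray:
    """Epidermal absorption mu_a,e = fm * mu_a,mel + mu_a,base (1/mm)."""
    return p.fm * lib.sample("melanin", grid) + lib.sample("baseline", grid)


def dermis_absorption(p: SkinTissueParams, lib: ChromophoreLibrary,
                      grid: WavelengthGrid) -> np.ndarray:
    """Dermal absorption from blood, bilirubin and cytochrome oxidase (1/mm).

    mu_a,d = fHb*mu_Hb + fHbO2*mu_HbO2 + fbrub*mu_brub
             + fCO*mu_CO + fCOO2*mu_COO2 + mu_a,base
    """
    for name in ("fHb", "fHbO2", "fbrub", "fCO", "fCOO2"):
        if getattr(p, name) < 0:
            raise ValueError(f"{name} must be non-negative")
    return (
        p.fHb * lib.sample("hb", grid)
        + p.fHbO2 * lib.sample("hbo2", grid)
        + p.fbrub * lib.sample("bilirubin", grid)
        + p.fCO * lib.sample("cco_reduced", grid)
        + p.fCOO2 * lib.sample("cco_oxidized", grid)
        + lib.sample("baseline", grid)
    )


def reduced_scattering(p: SkinTissueParams, grid: WavelengthGrid) -> np.ndarray:
    """Reduced scattering mu_s' (1/mm), Rayleigh + Mie power laws.

    mu_s'(lam) = a * [fRay*(lam/500)^-4 + (1-fRay)*(lam/500)^-b]
    """
    lam = grid.wavelengths / 500.0
    return p.a * (p.fRay * lam**-4.0 + (1.0 - p.fRay) * lam ** (-p.b))


def build_layers(p: SkinTissueParams, lib: ChromophoreLibrary,
                 grid: WavelengthGrid) -> list[LayerOpticalProperties]:
    """Assemble the epidermis/dermis optical-property stacks (top first)."""
    musp = reduced_scattering(p, grid)
    epi = LayerOpticalProperties(
        mua=epidermis_absorption(p, lib, grid), musp=musp,
        g=G_HENYEY_GREENSTEIN, n=N_TISSUE, d=p.de)
    der = LayerOpticalProperties(
        mua=dermis_absorption(p, lib, grid), musp=musp,
        g=G_HENYEY_GREENSTEIN, n=N_TISSUE, d=p.dd)
    return [epi, der]


def simulate_spectrum(p: SkinTissueParams,
                      lib: ChromophoreLibrary | None = None,
                      grid: WavelengthGrid | None = None,
                      quadrature_order: int = 16) -> np.ndarray:
    """Total diffuse reflectance spectrum of the two-layer skin model.

    Returns an array over the grid (default 61 bands), each value in [0, 1].
    """
    lib = lib or load_default_library()
    grid = grid or default_grid()
    layers = build_layers(p, lib, grid)
    refl, _ = adding_doubling_rt(layers, quadrature_order=quadrature_order,
                                 n_ambient=N_AMBIENT)
    return refl
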