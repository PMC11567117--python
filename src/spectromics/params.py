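"""Tissue-parameter state of the two-layer skin model.

The model has eleven parameters: epidermal melanin fraction ``fm``,
dermal blood fractions ``fHb``/``fHbO2``, molar concentrations of
bilirubin ``fbrub`` and reduced/oxidized cytochrome-c oxidase
``fCO``/``fCOO2``, the reduced-scattering amplitude ``a`` (1/mm at
500 nm), scattering power ``b``, Rayleigh fraction ``fRay``, and the
layer thicknesses ``de`` (epidermis) and ``dd`` (dermis), in mm.
Scattering parameters are shared by both layers; the dermis is treated
as effectively semi-infinite at the default thickness.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np

__all__ = [
    "SkinTissueParams",
    "LayerOpticalProperties",
    "PARAM_NAMES",
    "G_HENYEY_GREENSTEIN",
    "N_TISSUE",
    "N_AMBIENT",
    "DD_SEMI_INFINITE",
]

PARAM_NAMES = ("fm", "fHb", "fHbO2", "fbrub", "fCO", "fCOO2",
               "a", "b", "fRay", "de", "dd")

# Fixed optical conventions of the implementation (not model parameters):
# Henyey-Greenstein anisotropy and refractive indices.  The transport model
# is parameterized by the reduced scattering coefficient, so reflectance is
# insensitive to the particular g; 0.9 and 1.4 are the standard skin values.
G_HENYEY_GREENSTEIN = 0.9
N_TISSUE = 1.4
N_AMBIENT = 1.0
# Default dermis thickness (mm): thick enough that diffuse transmittance is
# negligible (< 1e-4) even in the most transparent band, i.e. semi-infinite.
DD_SEMI_INFINITE = 20.0


@dataclass(frozen=True)
class SkinTissueParams:
    fm: float = 0.02        # epidermal melanin volume fraction
    fHb: float = 0.015      # dermal deoxyhemoglobin (blood) volume fraction
    fHbO2: float = 0.012    # dermal oxyhemoglobin (blood) volume fraction
    fbrub: float = 0.0      # bilirubin molar concentration, mol/L
    fCO: float = 0.0        # reduced cytochrome-c oxidase, mol/L
    fCOO2: float = 0.0      # oxidized cytochrome-c oxidase, mol/L
    a: float = 2.0          # reduced scattering at 500 nm, 1/mm
    b: float = 1.2          # Mie scattering power
    fRay: float = 0.2       # Rayleigh fraction of reduced scattering
    de: float = 0.06        # epidermis thickness, mm
    dd: float = DD_SEMI_INFINITE  # dermis thickness, mm

    def __post_init__(self):
        for name in ("fm", "fHb", "fHbO2", "fRay"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("fbrub", "fCO", "fCOO2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.a <= 0:
            raise ValueError("scattering amplitude a must be positive")
        if self.de <= 0:
            raise ValueError("epidermis thickness de must be positive")
        if self.dd <= 0:
            raise ValueError("dermis thickness dd must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], float)

    @classmethod
    def from_array(cls, x) -> "SkinTissueParams":
        return cls(**{n: float(v) for n, v in zip(PARAM_NAMES, x)})

    def replace(self, **kw) -> "SkinTissueParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class LayerOpticalProperties:
    """Per-wavelength optical properties of one slab layer.

    mua and musp are arrays (1/mm) over the wavelength grid; g, n and the
    thickness d (mm) are scalars.
    """

    mua: np.ndarray
    musp: np.ndarray
    g: float = G_HENYEY_GREENSTEIN
    n: float = N_TISSUE
    d: float = 1.0

    def __post_init__(self):
        mua = np.atleast_1d(np.asarray(self.mua, float))
        musp = np.atleast_1d(np.asarray(self.musp, float))
        if mua.shape != musp.shape:
            raise ValueError("mua and musp must share a shape")
        if np.any(mua < 0) or np.any(musp < 0):
            raise ValueError("absorption and scattering must be non-negative")
        if not abs(self.g) < 1:
            raise ValueError("anisotropy g must satisfy |g| < 1")
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")
        if self.d <= 0:
            raise ValueError("layer thickness must be positive")
        object.__setattr__(self, "mua", mua)
        object.__setattr__(self, "musp", musp)

    @property
    def mus(self) -> np.ndarray:
        """Unreduced scattering coefficient musp / (1 - g)."""
        return self.musp / (1.0 - self.g)
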