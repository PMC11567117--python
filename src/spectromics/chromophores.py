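"""Chromophore absorption library for the two-layer skin model.

The packaged tables are synthetic reconstructions of published skin-optics
compilations (smooth interpolants through band-structure anchor values);
they carry the qualitative features the model relies on -- Soret band,
alpha/beta oxyhemoglobin bands, isosbestic crossings between 500 and
600 nm, melanin and baseline power/exponential decays -- and consistent
units.  Hemoglobin tables are whole-blood absorption (150 g/L) in 1/mm so
that ``fHb``/``fHbO2`` are blood volume fractions; bilirubin and
cytochrome-c-oxidase tables are 1/mm per mol/L so their coefficients are
molar concentrations.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .grids import WavelengthGrid

__all__ = ["ChromophoreLibrary", "load_default_library", "CHROMOPHORE_NAMES"]

CHROMOPHORE_NAMES = (
    "melanin",
    "hb",
    "hbo2",
    "bilirubin",
    "cco_reduced",
    "cco_oxidized",
    "baseline",
)

_FILES = {
    "melanin": "synthetic_melanin.tsv",
    "hb": "synthetic_hb.tsv",
    "hbo2": "synthetic_hbo2.tsv",
    "bilirubin": "synthetic_bilirubin.tsv",
    "cco_reduced": "synthetic_cco_reduced.tsv",
    "cco_oxidized": "synthetic_cco_oxidized.tsv",
    "baseline": "synthetic_baseline.tsv",
}


class CoverageError(ValueError):
    """Requested grid extends beyond the library's tabulated range."""


@dataclass(frozen=True)
class ChromophoreLibrary:
    """Per-wavelength absorption coefficients of the model chromophores.

    Attributes
    ----------
    wavelengths : tabulated wavelengths, nm
    mua : dict mapping chromophore name -> absorption coefficient array
        (1/mm, or 1/mm per mol/L for the molar species).
    """

    wavelengths: np.ndarray
    mua: dict

    def __post_init__(self):
        w = np.asarray(self.wavelengths, float)
        for name in CHROMOPHORE_NAMES:
            if name not in self.mua:
                raise ValueError(f"library is missing chromophore {name!r}")
            v = np.asarray(self.mua[name], float)
            if v.shape != w.shape:
                raise ValueError(f"table for {name!r} does not match wavelengths")
            if np.any(v < 0):
                raise ValueError(f"negative absorption in table {name!r}")

    def covers(self, grid: WavelengthGrid) -> bool:
        return self.wavelengths[0] <= grid.lo and grid.hi <= self.wavelengths[-1]

    def sample(self, name: str, grid: WavelengthGrid) -> np.ndarray:
        """Absorption coefficient of ``name`` interpolated onto ``grid``."""
        if name not in self.mua:
            raise KeyError(name)
        if not self.covers(grid):
            raise CoverageError(
                f"grid {grid.lo}-{grid.hi} nm outside library coverage "
                f"{self.wavelengths[0]}-{self.wavelengths[-1]} nm"
            )
        return np.interp(grid.wavelengths, self.wavelengths, self.mua[name])


def _read_table(fname: str):
    ref = resources.files("spectromics.data.chromophores").joinpath(fname)
    rows = np.loadtxt(str(ref), comments="#")
    return rows[:, 0], rows[:, 1]


def load_default_library() -> ChromophoreLibrary:
    """Load the packaged chromophore tables (400-800 nm, 2 nm steps)."""
    tables = {}
    wav = None
    for name, fname in _FILES.items():
        w, v = _read_table(fname)
        if wav is None:
            wav = w
        elif not np.array_equal(w, wav):
            raise ValueError("packaged tables disagree on the wavelength axis")
        tables[name] = v
    return ChromophoreLibrary(wavelengths=wav, mua=tables)
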