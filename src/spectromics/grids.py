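"""Wavelength grids for hyperspectral cubes and forward-model spectra."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WavelengthGrid", "default_grid"]


@dataclass(frozen=True)
class WavelengthGrid:
    """A strictly increasing set of wavelengths, in nanometers.

    The working grid of the analysis is 450-750 nm in 5 nm steps
    (61 samples), the visible band retained after spectral reduction.
    """

    wavelengths: np.ndarray = field(
        default_factory=lambda: np.arange(450.0, 755.0, 5.0)
    )

    def __post_init__(self):
        w = np.asarray(self.wavelengths, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise ValueError("wavelength grid must be a 1-D array with >= 2 entries")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", w)

    def __len__(self) -> int:
        return self.wavelengths.size

    def __eq__(self, other) -> bool:
        return isinstance(other, WavelengthGrid) and np.array_equal(
            self.wavelengths, other.wavelengths
        )

    def __hash__(self) -> int:
        return hash(self.wavelengths.tobytes())

    @property
    def lo(self) -> float:
        return float(self.wavelengths[0])

    @property
    def hi(self) -> float:
        return float(self.wavelengths[-1])


def default_grid() -> WavelengthGrid:
    """The 450:5:750 nm analysis grid (61 bands)."""
    return WavelengthGrid()
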