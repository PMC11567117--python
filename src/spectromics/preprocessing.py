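"""Raw-cube conditioning: reflectance normalization, spectral-angle
background removal, spectral/spatial reduction and the erythema-index
contrast image used for tumor visualization.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from skimage import exposure, measure

from .grids import WavelengthGrid, default_grid

__all__ = [
    "HyperCube",
    "TissueMask",
    "normalize_reflectance",
    "spectral_angle",
    "remove_background",
    "reduce_cube",
    "erythema_index",
    "prepare_ei_display",
    "SAM_THRESHOLD_DEG",
]

# Spectral-angle threshold (degrees) separating tissue from background:
# pixels whose spectra make an angle larger than this with the tissue
# reference are background.  Background pixels are essentially reference
# noise after dark subtraction, so their angles concentrate near 90 deg.
SAM_THRESHOLD_DEG = 78.46

LABEL_BACKGROUND, LABEL_HEALTHY, LABEL_TUMOR = 0, 1, 2


@dataclass
class HyperCube:
    """rows x cols x bands reflectance cube with its wavelength grid."""

    data: np.ndarray
    grid: WavelengthGrid
    stage: str = "raw"  # raw | normalized | reduced

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise ValueError("cube must be rows x cols x bands")
        if self.data.shape[2] != len(self.grid):
            raise ValueError("band count must equal the grid length")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class TissueMask:
    """Boolean tissue map plus a background/healthy/tumor label map."""

    tissue: np.ndarray
    labels: np.ndarray = None

    def __post_init__(self):
        self.tissue = np.asarray(self.tissue, bool)
        if self.labels is None:
            self.labels = np.where(self.tissue, LABEL_HEALTHY,
                                   LABEL_BACKGROUND).astype(np.uint8)
        self.labels = np.asarray(self.labels, np.uint8)
        if self.labels.shape != self.tissue.shape:
            raise ValueError("labels and tissue mask must share a shape")
        if np.any((self.labels > 0) & ~self.tissue):
            raise ValueError("labeled pixels must lie inside the tissue mask")

    @property
    def healthy(self):
        return self.labels == LABEL_HEALTHY

    @property
    def tumor(self):
        return self.labels == LABEL_TUMOR


class DegenerateReferenceError(ValueError):
    pass


def normalize_reflectance(raw, dark, white, grid=None,
                          clip: bool = True) -> HyperCube:
    """Reflectance normalization R = (raw - dark) / (white - dark).

    dark/white may be full cubes or per-band vectors.  Values are clipped
    to [0, 1] afterwards (sensor noise can push past the white standard).
    """
    raw = np.asarray(raw, float)
    dark = np.broadcast_to(np.asarray(dark, float), raw.shape)
    white = np.broadcast_to(np.asarray(white, float), raw.shape)
    denom = white - dark
    if np.any(denom <= 0):
        raise DegenerateReferenceError(
            "white reference must exceed dark current everywhere")
    out = (raw - dark) / denom
    if clip:
        out = np.clip(out, 0.0, 1.0)
    grid = grid or WavelengthGrid(np.arange(raw.shape[2], dtype=float) + 1.0)
    return HyperCube(out, grid, stage="normalized")


def spectral_angle(s1, s2) -> float:
    """Angle between two spectra in degrees (scale invariant)."""
    s1 = np.asarray(s1, float)
    s2 = np.asarray(s2, float)
    if s1.shape != s2.shape:
        raise ValueError("spectra must share a length")
    n1 = np.linalg.norm(s1)
    n2 = np.linalg.norm(s2)
    if n1 == 0 or n2 == 0:
        raise ValueError("spectral angle undefined for a zero spectrum")
    c = np.clip(np.dot(s1, s2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def remove_background(cube: HyperCube, reference_spectrum=None,
                      threshold_deg: float = SAM_THRESHOLD_DEG,
                      clean: bool = True, center: bool = True) -> TissueMask:
    """Segment tissue from background by spectral angle to a tissue
    reference.

    A pixel is tissue iff its angle to the reference is <= threshold.
    Default reference: the mean spectrum of the brightest-quartile pixels
    (tissue dominates the bright end once the background is dark-
    subtracted).  With ``center=True`` (default) each spectrum has its
    mean removed before the angle is taken, making the measure sensitive
    to spectral shape rather than overall albedo: a flat, nearly dark
    background then scatters around 90 degrees while tissue stays far
    below the threshold.  The largest connected tissue component is kept.
    """
    data = cube.data
    rows, cols, bands = data.shape
    flat = data.reshape(-1, bands)
    if reference_spectrum is None:
        brightness = flat.mean(axis=1)
        bright = flat[brightness >= np.quantile(brightness, 0.75)]
        reference_spectrum = bright.mean(axis=0)
    ref = np.asarray(reference_spectrum, float)
    if center:
        flat = flat - flat.mean(axis=1, keepdims=True)
        ref = ref - ref.mean()
    nref = np.linalg.norm(ref)
    if nref == 0:
        raise ValueError("reference spectrum has zero norm")
    norms = np.linalg.norm(flat, axis=1)
    cosang = np.zeros(flat.shape[0])
    ok = norms > 0
    cosang[ok] = flat[ok] @ ref / (norms[ok] * nref)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ang[~ok] = 180.0
    tissue = (ang <= threshold_deg).reshape(rows, cols)
    if clean and tissue.any():
        lab = measure.label(tissue, connectivity=2)
        largest = np.argmax(np.bincount(lab[lab > 0]))
        tissue = lab == largest
    if not tissue.any():
        warnings.warn("background removal produced an empty tissue mask")
    return TissueMask(tissue=tissue)


def reduce_cube(cube: HyperCube, target_grid: WavelengthGrid | None = None,
                spatial_bin: int = 2) -> HyperCube:
    """Spectral reduction to 450:5:750 nm and 2x2 mean spatial binning.

    Each target band is the mean of native bands within half a step of
    the band center (pass-through when the cube is already on the target
    grid).  Trailing rows/cols that do not fill a bin are dropped.
    """
    target = target_grid or default_grid()
    native = cube.grid.wavelengths
    if native[0] > target.lo or native[-1] < target.hi:
        raise ValueError(
            f"native grid {native[0]}-{native[-1]} nm does not cover "
            f"the target range {target.lo}-{target.hi} nm")
    step = np.median(np.diff(target.wavelengths))
    data = cube.data
    if np.array_equal(native, target.wavelengths):
        spectral = data
    else:
        spectral = np.empty(data.shape[:2] + (len(target),))
        for i, wc in enumerate(target.wavelengths):
            sel = np.abs(native - wc) <= step / 2.0
            if not sel.any():
                sel = np.array([np.argmin(np.abs(native - wc))])
            spectral[:, :, i] = data[:, :, sel].mean(axis=2)
    if spatial_bin > 1:
        r = (spectral.shape[0] // spatial_bin) * spatial_bin
        c = (spectral.shape[1] // spatial_bin) * spatial_bin
        s = spectral[:r, :c]
        s = s.reshape(r // spatial_bin, spatial_bin,
                      c // spatial_bin, spatial_bin, -1).mean(axis=(1, 3))
        spectral = s
    return HyperCube(spectral, target, stage="reduced")


@dataclass(frozen=True)
class EIWindows:
    """Red/green reflectance windows of the erythema index, nm."""
    red: tuple = (610.0, 700.0)
    green: tuple = (510.0, 580.0)


def erythema_index(cube: HyperCube, windows: EIWindows = EIWindows()):
    """Erythema-index map: mean red-window over mean green-window
    reflectance.  Blood absorbs green strongly, so blood-rich (erythematous)
    tissue has a depressed green window and a larger index."""
    w = cube.grid.wavelengths
    red = (w >= windows.red[0]) & (w <= windows.red[1])
    green = (w >= windows.green[0]) & (w <= windows.green[1])
    if not red.any() or not green.any():
        raise ValueError("EI windows fall outside the cube's grid")
    red_m = cube.data[:, :, red].mean(axis=2)
    green_m = cube.data[:, :, green].mean(axis=2)
    return red_m / np.maximum(green_m, 1e-9)


def prepare_ei_display(ei_map, median_size: int = 3,
                       clip_limit: float = 0.02) -> np.ndarray:
    """Median-filter then adaptive-histogram-equalize an EI map for
    display; output in [0, 1]."""
    m = median_filter(np.asarray(ei_map, float), size=median_size)
    lo, hi = m.min(), m.max()
    if hi - lo < 1e-12:
        return np.zeros_like(m)
    m = (m - lo) / (hi - lo)
    return exposure.equalize_adapthist(m, clip_limit=clip_limit)
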