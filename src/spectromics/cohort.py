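"""Synthetic longitudinal tumor-imaging cohort.

Emulates the design of a 14-day murine CT26 study: six mice imaged on
days {0, 1-3, 6-10, 13-14} (11 sessions each, 66 cubes), tumors absent
on day 0 and growing thereafter, two mice held out for validation.
Each scene is a smooth healthy parameter field with an elliptical tumor
whose hemoglobin and oxygenation follow the study's reported
trajectories: healthy total hemoglobin steady around 2.7 +/- 1.4 %, and
tumor oxygenation rising from 28.2 % (day 1) to a 52.9 % peak (day 9)
before declining, with tumor hemoglobin slowly increasing.  Scenes are
rendered to raw hyperspectral cubes through the forward model with
multiplicative noise plus an additive floor and synthetic white/dark
reference frames, so the full preprocessing-inversion chain is exercised
end to end.

The printed dispersions are realized chiefly as intra-region pixel
heterogeneity, with a smaller between-subject jitter, so that cohort
means are stable study conditions rather than seed lottery.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import norm

from .chromophores import load_default_library
from .grids import WavelengthGrid, default_grid
from .inversion import ParameterMaps
from .lut import ReflectanceLUT, _LibrarySamples, build_default_lut
from .optics import simulate_spectrum
from .params import DD_SEMI_INFINITE, PARAM_NAMES, SkinTissueParams
from .preprocessing import (
    LABEL_BACKGROUND,
    LABEL_HEALTHY,
    LABEL_TUMOR,
    HyperCube,
    TissueMask,
)

__all__ = ["CohortDesign", "TumorTrajectory", "Cohort", "CohortImage",
           "generate_scene", "render_cube", "generate_cohort"]

DEFAULT_DAYS = (0, 1, 2, 3, 6, 7, 8, 9, 10, 13, 14)


@dataclass(frozen=True)
class CohortDesign:
    """Study geometry: subjects, imaging days, split, scene and noise."""

    n_mice: int = 6
    days: tuple = DEFAULT_DAYS
    n_validation: int = 2
    scene_shape: tuple = (48, 64)     # rows x cols, post-binning
    oversample: int = 2               # native render = shape * oversample
    noise: float = 0.01               # multiplicative, native resolution
    noise_floor: float = 0.002        # additive reflectance floor

    def __post_init__(self):
        if tuple(sorted(self.days)) != tuple(self.days):
            raise ValueError("days must be sorted")
        if 0 not in self.days:
            raise ValueError("day 0 (injection day) must be present")
        if not 0 < self.n_validation < self.n_mice:
            raise ValueError("validation mice must be a strict subset")

    @property
    def validation_mice(self) -> tuple:
        return tuple(range(self.n_mice - self.n_validation, self.n_mice))

    @property
    def training_mice(self) -> tuple:
        return tuple(range(self.n_mice - self.n_validation))


@dataclass(frozen=True)
class TumorTrajectory:
    """Per-day generative targets, all in percent (radii in pixels).

    Tumor oxygenation interpolates the anchors; hemoglobin ramps
    linearly over the study; the radius grows roughly one pixel a day
    and is zero on day 0.
    """

    healthy_thb: float = 2.7
    healthy_thb_pixel_sd: float = 1.3
    healthy_thb_subject_sd: float = 0.35
    healthy_sto2: float = 38.0
    healthy_sto2_pixel_sd: float = 7.0
    healthy_sto2_subject_sd: float = 2.0
    tumor_thb_day1: float = 3.0
    tumor_thb_day14: float = 6.0
    tumor_thb_pixel_sd: float = 1.2
    tumor_thb_subject_sd: float = 0.3
    tumor_sto2_anchors: tuple = ((1.0, 28.2), (9.0, 52.9), (14.0, 45.0))
    tumor_sto2_pixel_sd_anchors: tuple = ((1.0, 8.7), (9.0, 13.8),
                                          (14.0, 12.0))
    tumor_sto2_subject_sd: float = 1.5
    radius_day1: float = 3.0
    radius_growth: float = 0.85       # pixels per day

    def tumor_sto2(self, day: float) -> float:
        d, v = zip(*self.tumor_sto2_anchors)
        return float(np.interp(day, d, v))

    def tumor_sto2_pixel_sd(self, day: float) -> float:
        d, v = zip(*self.tumor_sto2_pixel_sd_anchors)
        return float(np.interp(day, d, v))

    def tumor_thb(self, day: float) -> float:
        return float(np.interp(day, [1.0, 14.0],
                               [self.tumor_thb_day1, self.tumor_thb_day14]))

    def tumor_radius(self, day: float) -> float:
        if day <= 0:
            return 0.0
        return self.radius_day1 + self.radius_growth * (day - 1.0)


def _grf(shape, corr_length, rng, region=None):
    """Smoothed Gaussian random field with zero mean and unit variance.

    When ``region`` is given the field is standardized over that region,
    so the region mean realizes its drawn target exactly: without this,
    a small region inside a correlated field inherits a large random
    offset and the per-day targets would not be met.
    """
    f = gaussian_filter(rng.standard_normal(shape), corr_length,
                        mode="reflect")
    sel = f[region] if region is not None else f
    sd = sel.std()
    if sd == 0:
        return f - sel.mean()
    return (f - sel.mean()) / sd


# constant scene values for the parameters the per-pixel fit holds fixed
_FIXED = {"fbrub": 0.0, "fCO": 0.0, "fCOO2": 0.0, "fRay": 0.2,
          "de": 0.06, "dd": DD_SEMI_INFINITE}


def generate_scene(mouse: int, day: float, design: CohortDesign,
                   trajectory: TumorTrajectory, rng) -> tuple:
    """Ground-truth (ParameterMaps, TissueMask) for one imaging session.

    The tissue is a large ellipse on a dark background; the tumor is a
    smaller ellipse whose center is jittered per mouse.  Healthy melanin
    has a near-uniform marginal over a wide range (pigment/follicle
    mottle) while tumor melanin is tightly peaked, echoing the lower
    melanin-entropy reported inside tumors; tumor fields also use a
    shorter correlation length and slightly different scattering.
    """
    rows, cols = design.scene_shape
    radius = trajectory.tumor_radius(day)
    if radius > min(rows, cols) / 2.0 - 2.0:
        raise ValueError(f"tumor radius {radius:.1f} exceeds the scene")
    yy, xx = np.mgrid[:rows, :cols]
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    tissue = (((yy - cy) / (0.44 * rows)) ** 2
              + ((xx - cx) / (0.46 * cols)) ** 2) <= 1.0

    tumor = np.zeros_like(tissue)
    if radius > 0:
        tcy = cy + rng.uniform(-0.12, 0.12) * rows
        tcx = cx + rng.uniform(-0.12, 0.12) * cols
        ecc = rng.uniform(0.85, 1.18)
        tumor = (((yy - tcy) / radius) ** 2
                 + ((xx - tcx) / (radius * ecc)) ** 2) <= 1.0
        tumor &= tissue

    healthy = tissue & ~tumor

    # subject/day-level draws around the trajectory targets
    thb_h = max(rng.normal(trajectory.healthy_thb,
                           trajectory.healthy_thb_subject_sd), 0.8)
    sto2_h = np.clip(rng.normal(trajectory.healthy_sto2,
                                trajectory.healthy_sto2_subject_sd), 5, 90)
    thb_t = max(rng.normal(trajectory.tumor_thb(day),
                           trajectory.tumor_thb_subject_sd), 1.0)
    sto2_t = np.clip(rng.normal(trajectory.tumor_sto2(day),
                                trajectory.tumor_sto2_subject_sd), 5, 95)

    shape = (rows, cols)
    thb = np.clip(thb_h + trajectory.healthy_thb_pixel_sd
                  * _grf(shape, 5, rng, healthy), 0.4, 14.0)
    sto2 = np.clip(sto2_h + trajectory.healthy_sto2_pixel_sd
                   * _grf(shape, 5, rng, healthy), 3.0, 97.0)
    # healthy melanin: probit-flattened field -> near-uniform marginal
    fm = 0.012 + 0.016 * norm.cdf(_grf(shape, 4, rng, healthy))
    a = np.clip(2.0 + 0.18 * _grf(shape, 5, rng, healthy), 0.6, 4.8)
    b = np.clip(1.2 + 0.10 * _grf(shape, 5, rng, healthy), 0.1, 2.8)

    if tumor.any():
        thb_map_t = np.clip(thb_t + trajectory.tumor_thb_pixel_sd
                            * _grf(shape, 2, rng, tumor), 0.4, 14.0)
        sto2_map_t = np.clip(sto2_t + trajectory.tumor_sto2_pixel_sd(day)
                             * _grf(shape, 2, rng, tumor), 3.0, 97.0)
        fm_t = np.clip(0.020 + 0.0018 * _grf(shape, 2, rng, tumor),
                       0.001, 0.09)
        a_t = np.clip(2.35 + 0.22 * _grf(shape, 2, rng, tumor), 0.6, 4.8)
        b_t = np.clip(0.95 + 0.12 * _grf(shape, 2, rng, tumor), 0.1, 2.8)
        thb[tumor] = thb_map_t[tumor]
        sto2[tumor] = sto2_map_t[tumor]
        fm[tumor] = fm_t[tumor]
        a[tumor] = a_t[tumor]
        b[tumor] = b_t[tumor]

    fhbo2 = thb / 100.0 * sto2 / 100.0
    fhb = thb / 100.0 * (1.0 - sto2 / 100.0)

    params = {}
    for name in PARAM_NAMES:
        m = np.full(shape, np.nan)
        params[name] = m
    params["fm"][tissue] = fm[tissue]
    params["fHb"][tissue] = fhb[tissue]
    params["fHbO2"][tissue] = fhbo2[tissue]
    params["a"][tissue] = a[tissue]
    params["b"][tissue] = b[tissue]
    for name, val in _FIXED.items():
        params[name][tissue] = val

    labels = np.full(shape, LABEL_BACKGROUND, np.uint8)
    labels[healthy] = LABEL_HEALTHY
    labels[tumor] = LABEL_TUMOR
    mask = TissueMask(tissue=tissue, labels=labels)
    maps = ParameterMaps(params=params, residual=np.zeros(shape),
                         valid=tissue.copy(),
                         converged=np.ones(shape, bool))
    return maps, mask


# reference frames: smooth lamp/white-standard shape and dark current,
# in raw counts normalized to a unit-scale sensor
_BG_REFLECTANCE = 0.006


def _white_dark(grid: WavelengthGrid):
    lam = grid.wavelengths
    white = 0.85 * (1.0 - 0.25 * ((lam - 580.0) / 300.0) ** 2)
    dark = np.full(lam.shape, 0.02)
    return white, dark


def render_cube(scene: ParameterMaps, mask: TissueMask,
                design: CohortDesign, rng,
                grid: WavelengthGrid | None = None,
                lut: ReflectanceLUT | None = None,
                forward: str = "lut",
                lib=None) -> dict:
    """Render a scene to a raw cube plus white/dark reference frames.

    The scene is upsampled by the design's oversample factor (pixel
    replication), converted to reflectance through the forward model
    (dense interpolated table by default, exact adding-doubling with
    forward="exact"), noised, and converted to raw counts so that
    reflectance normalization is exercised.  Background pixels carry a
    flat, nearly dark spectrum.
    """
    grid = grid or default_grid()
    lib = lib or load_default_library()
    ov = design.oversample
    rows, cols = scene.shape
    tissue = mask.tissue

    theta = np.stack([scene.map(n)[tissue] for n in PARAM_NAMES], axis=1)
    if forward == "lut":
        lut = lut or build_default_lut(de=float(_FIXED["de"]))
        samples = _LibrarySamples(lib, grid)
        refl_t = lut.evaluate(*samples.optical_properties(theta))
    elif forward == "exact":
        refl_t = np.stack([
            simulate_spectrum(SkinTissueParams.from_array(t), lib, grid)
            for t in theta])
    else:
        raise ValueError(f"unknown forward {forward!r}")

    refl = np.full((rows, cols, len(grid)), _BG_REFLECTANCE)
    refl[tissue] = refl_t

    native = np.repeat(np.repeat(refl, ov, axis=0), ov, axis=1)
    noisy = (native * (1.0 + design.noise
                       * rng.standard_normal(native.shape))
             + design.noise_floor * rng.standard_normal(native.shape))
    white, dark = _white_dark(grid)
    raw = dark + np.clip(noisy, 0.0, None) * (white - dark)
    return {
        "raw": HyperCube(raw, grid, stage="raw"),
        "dark": dark,
        "white": white,
        "reflectance_clean": refl,
    }


@dataclass
class CohortImage:
    mouse: int
    day: float
    split: str
    raw: HyperCube
    dark: np.ndarray
    white: np.ndarray
    truth_maps: ParameterMaps
    truth_mask: TissueMask


@dataclass
class Cohort:
    design: CohortDesign
    trajectory: TumorTrajectory
    seed: int
    images: list

    def manifest(self) -> pd.DataFrame:
        rows = []
        for im in self.images:
            rows.append(dict(mouse=im.mouse, day=im.day, split=im.split,
                             has_tumor=bool(im.truth_mask.tumor.any())))
        return pd.DataFrame(rows)


def generate_cohort(design: CohortDesign | None = None,
                    trajectory: TumorTrajectory | None = None,
                    seed: int = 0,
                    forward: str = "lut",
                    lut: ReflectanceLUT | None = None) -> Cohort:
    """Generate the full virtual experiment.

    Returns a Cohort whose default design holds 66 raw cubes and whose
    labeled observations number 126 (66 healthy + 60 tumor): 84 rows
    from the four training/testing mice, 42 from the two validation
    mice.  Deterministic per seed; distinct seeds share the design
    counts and differ in fields and noise.
    """
    design = design or CohortDesign()
    trajectory = trajectory or TumorTrajectory()
    if forward == "lut":
        lut = lut or build_default_lut(de=float(_FIXED["de"]))
    images = []
    val = set(design.validation_mice)
    for mouse in range(design.n_mice):
        for day in design.days:
            child = np.random.default_rng(
                np.random.SeedSequence((seed, mouse, int(day * 10))))
            maps, mask = generate_scene(mouse, day, design, trajectory, child)
            rend = render_cube(maps, mask, design, child, lut=lut,
                               forward=forward)
            images.append(CohortImage(
                mouse=mouse, day=day,
                split="validation" if mouse in val else "train",
                raw=rend["raw"], dark=rend["dark"], white=rend["white"],
                truth_maps=maps, truth_mask=mask))
    return Cohort(design=design, trajectory=trajectory, seed=seed,
                  images=images)
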