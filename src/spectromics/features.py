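"""Radiomic features over fitted tissue-parameter maps.

Ten parameters are summarized per tissue region: fm, fHb, fHbO2, THB,
StO2, fbrub, fCO, fCOO2, a and b.  Eight statistics are taken per
parameter -- mean, standard deviation, skewness, kurtosis, histogram
entropy, co-occurrence contrast, histogram energy and co-occurrence
homogeneity -- yielding the 80-column observation table.  Column ``k``
encodes statistic block ``(k-1)//10`` and parameter ``(k-1)%10``:
1-10 means, 11-20 SDs, 21-30 skewness, 31-40 kurtosis, 41-50 entropy,
51-60 contrast, 61-70 energy, 71-80 homogeneity.  Region minima and
maxima are deliberately not features: the fit bounds predetermine them.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter

from .inversion import ParameterMaps
from .params import PARAM_NAMES

__all__ = [
    "FeatureConfig",
    "FeatureTable",
    "FEATURE_PARAMS",
    "FEATURE_STATS",
    "feature_index",
    "feature_descriptor",
    "thb_map",
    "sto2_map",
    "first_order_features",
    "glcm_features",
    "region_features",
    "build_feature_table",
    "gaussian_smooth_maps",
]

FEATURE_PARAMS = ("fm", "fHb", "fHbO2", "THB", "StO2",
                  "fbrub", "fCO", "fCOO2", "a", "b")
FEATURE_STATS = ("mean", "sd", "skewness", "kurtosis",
                 "entropy", "contrast", "energy", "homogeneity")

# GLCM offsets at distance delta (infinity norm) for 0/45/90/135 degrees
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class FeatureConfig:
    """Quantization and co-occurrence settings.

    ng : number of gray levels for histogram and GLCM quantization
    delta : co-occurrence offset distance in pixels (infinity norm)
    angles : co-occurrence angles in degrees, averaged
    """

    ng: int = 32
    delta: int = 1
    angles: tuple = (0, 45, 90, 135)

    def __post_init__(self):
        if self.ng < 2:
            raise ValueError("ng must be >= 2")
        if self.delta < 1:
            raise ValueError("delta must be >= 1")
        if any(a not in _ANGLE_OFFSETS for a in self.angles):
            raise ValueError("angles must be among 0, 45, 90, 135")


def feature_index(stat: str, param: str) -> int:
    """1-based column index of (statistic, parameter)."""
    return FEATURE_STATS.index(stat) * 10 + FEATURE_PARAMS.index(param) + 1


def feature_descriptor(index: int) -> tuple:
    """(statistic, parameter) of a 1-based column index."""
    if not 1 <= index <= 80:
        raise ValueError("feature index must be in 1..80")
    return FEATURE_STATS[(index - 1) // 10], FEATURE_PARAMS[(index - 1) % 10]


def thb_map(maps: ParameterMaps) -> np.ndarray:
    """Total hemoglobin THB = 100 * (fHb + fHbO2), percent."""
    return 100.0 * (maps.map("fHb") + maps.map("fHbO2"))


def sto2_map(maps: ParameterMaps) -> np.ndarray:
    """Oxygen saturation StO2 = 100 * fHbO2 / (fHb + fHbO2), percent.

    NaN (masked) where total hemoglobin is zero.
    """
    fhb = maps.map("fHb")
    fhbo2 = maps.map("fHbO2")
    tot = fhb + fhbo2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(tot > 0, 100.0 * fhbo2 / np.where(tot > 0, tot, 1.0),
                       np.nan)
    return out


def _quantize(values, ng):
    lo = values.min()
    hi = values.max()
    if hi - lo <= 0:
        return np.zeros(values.shape, np.intp), lo, hi
    q = ((values - lo) / (hi - lo) * ng).astype(np.intp)
    return np.clip(q, 0, ng - 1), lo, hi


def first_order_features(map_, mask, cfg: FeatureConfig = FeatureConfig()):
    """(mean, sd, skewness, kurtosis, entropy, energy) over region pixels.

    Moments are sample statistics (SD with ddof=1, Fisher-Pearson
    skewness, Pearson non-excess kurtosis); a constant region takes
    skewness = kurtosis = 0 by convention.  Entropy (bits) and energy are
    computed from the ng-level histogram over the region's min-max range.
    """
    mask = np.asarray(mask, bool)
    vals = np.asarray(map_, float)[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("region must contain at least 2 valid pixels")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if sd > 0:
        skew = float(stats.skew(vals))
        kurt = float(stats.kurtosis(vals, fisher=False))
    else:
        skew = 0.0
        kurt = 0.0
    q, lo, hi = _quantize(vals, cfg.ng)
    p = np.bincount(q, minlength=cfg.ng).astype(float)
    p /= p.sum()
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    energy = float((p**2).sum())
    return mean, sd, skew, kurt, entropy, energy


def glcm_features(map_, mask, cfg: FeatureConfig = FeatureConfig()):
    """(contrast, homogeneity) from the symmetric normalized GLCM.

    The co-occurrence matrix is built per angle at offset distance delta
    (infinity norm) from pairs lying fully inside the region, symmetrized
    and normalized; features are averaged over angles with valid pairs.
    scikit-image's GLCM cannot restrict to an irregular region mask, so
    pair counting is done directly here.
    """
    mask = np.asarray(mask, bool)
    m = np.asarray(map_, float)
    region = mask & np.isfinite(m)
    if not region.any():
        raise ValueError("empty region")
    q = np.zeros(m.shape, np.intp)
    qv, _, _ = _quantize(m[region], cfg.ng)
    q[region] = qv
    contrasts = []
    homogeneities = []
    levels = np.arange(cfg.ng)
    di_abs = np.abs(levels[:, None] - levels[None, :]).astype(float)
    for ang in cfg.angles:
        dr, dc = _ANGLE_OFFSETS[ang]
        dr *= cfg.delta
        dc *= cfg.delta
        rows, cols = m.shape
        r0s, r0e = max(0, -dr), min(rows, rows - dr)
        c0s, c0e = max(0, -dc), min(cols, cols - dc)
        src = region[r0s:r0e, c0s:c0e]
        dst = region[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
        both = src & dst
        if not both.any():
            continue
        a = q[r0s:r0e, c0s:c0e][both]
        b = q[r0s + dr:r0e + dr, c0s + dc:c0e + dc][both]
        counts = np.bincount(a * cfg.ng + b, minlength=cfg.ng * cfg.ng)
        glcm = counts.reshape(cfg.ng, cfg.ng).astype(float)
        glcm = glcm + glcm.T  # symmetrize
        p = glcm / glcm.sum()
        contrasts.append(float((di_abs**2 * p).sum()))
        homogeneities.append(float((p / (1.0 + di_abs)).sum()))
    if not contrasts:
        raise ValueError(
            f"no valid pixel pairs at offset {cfg.delta} in any direction")
    return float(np.mean(contrasts)), float(np.mean(homogeneities))


def _parameter_images(maps: ParameterMaps) -> dict:
    imgs = {n: maps.map(n) for n in ("fm", "fHb", "fHbO2",
                                     "fbrub", "fCO", "fCOO2", "a", "b")}
    imgs["THB"] = thb_map(maps)
    imgs["StO2"] = sto2_map(maps)
    return {n: imgs[n] for n in FEATURE_PARAMS}


def region_features(maps: ParameterMaps, region_mask,
                    cfg: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """The 80-feature vector of one tissue region, in column order."""
    imgs = _parameter_images(maps)
    out = np.empty(80)
    for param, img in imgs.items():
        mean, sd, skew, kurt, entropy, energy = first_order_features(
            img, region_mask, cfg)
        contrast, homo = glcm_features(img, region_mask, cfg)
        for stat, val in (("mean", mean), ("sd", sd), ("skewness", skew),
                          ("kurtosis", kurt), ("entropy", entropy),
                          ("contrast", contrast), ("energy", energy),
                          ("homogeneity", homo)):
            out[feature_index(stat, param) - 1] = val
    return out


@dataclass
class FeatureTable:
    """Observation table: one row per (subject, day, tissue class).

    ``data`` holds metadata columns (subject, day, tissue_class, split)
    followed by feature columns f01..f80 in the invariant layout.
    """

    data: pd.DataFrame

    FEATURE_COLUMNS = tuple(f"f{i:02d}" for i in range(1, 81))

    def __post_init__(self):
        missing = [c for c in self.FEATURE_COLUMNS if c not in self.data]
        if missing:
            raise ValueError(f"missing feature columns: {missing[:3]}...")

    @property
    def features(self) -> np.ndarray:
        return self.data[list(self.FEATURE_COLUMNS)].to_numpy()

    @property
    def labels(self) -> np.ndarray:
        """Binary labels, tumor = 1."""
        return (self.data["tissue_class"] == "tumor").to_numpy().astype(int)

    @property
    def subjects(self) -> np.ndarray:
        return self.data["subject"].to_numpy()

    def layout(self) -> dict:
        return {i: feature_descriptor(i) for i in range(1, 81)}

    def to_csv(self, path):
        self.data.to_csv(path, index=False)
        schema = {f"f{i:02d}": {"index": i,
                                "statistic": feature_descriptor(i)[0],
                                "parameter": feature_descriptor(i)[1]}
                  for i in range(1, 81)}
        with open(str(path) + ".schema.json", "w") as fh:
            json.dump(schema, fh, indent=1)


def build_feature_table(observations,
                        cfg: FeatureConfig = FeatureConfig()) -> FeatureTable:
    """Assemble the 80-column table from per-image fitted maps.

    observations : iterable of dicts with keys ``subject``, ``day``,
        ``maps`` (ParameterMaps), ``mask`` (TissueMask) and optionally
        ``split``.  Each image contributes a healthy row, and a tumor row
        when the tumor mask is non-empty.
    """
    rows = []
    for obs in observations:
        maps = obs["maps"]
        mask = obs["mask"]
        meta = {"subject": obs["subject"], "day": obs["day"],
                "split": obs.get("split", "train")}
        healthy = mask.healthy & maps.valid
        if not healthy.any():
            raise ValueError(
                f"no healthy pixels for subject {meta['subject']} "
                f"day {meta['day']}")
        regions = [("healthy", healthy)]
        tumor = mask.tumor & maps.valid
        if tumor.any():
            regions.append(("tumor", tumor))
        for cls, region in regions:
            vec = region_features(maps, region, cfg)
            row = dict(meta, tissue_class=cls)
            row.update({f"f{i:02d}": vec[i - 1] for i in range(1, 81)})
            rows.append(row)
    df = pd.DataFrame(rows)
    cols = ["subject", "day", "tissue_class", "split"] + \
        list(FeatureTable.FEATURE_COLUMNS)
    return FeatureTable(df[cols])


def gaussian_smooth_maps(maps: ParameterMaps, sigma: float) -> ParameterMaps:
    """Masked Gaussian smoothing of every fitted parameter map.

    sigma = 0 returns a bitwise-identical copy.  Smoothing is normalized
    within the valid mask (no leakage from invalid pixels), so constant
    maps are unchanged and interior means are preserved.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return ParameterMaps(params={n: m.copy() for n, m in
                                     maps.params.items()},
                             residual=maps.residual.copy(),
                             valid=maps.valid.copy(),
                             converged=maps.converged.copy())
    valid = maps.valid
    wnorm = gaussian_filter(valid.astype(float), sigma)
    out = {}
    for name in PARAM_NAMES:
        m = maps.map(name)
        filled = np.where(valid, m, 0.0)
        sm = gaussian_filter(filled, sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            res = np.where(valid & (wnorm > 1e-12), sm / wnorm, np.nan)
        out[name] = res
    return ParameterMaps(params=out, residual=maps.residual.copy(),
                         valid=valid.copy(), converged=maps.converged.copy())
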