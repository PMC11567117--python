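"""End-to-end study pipeline over a (synthetic or loaded) cohort.

Each raw cube is normalized against its reference frames, reduced to the
450-750 nm grid with 2x2 binning, segmented from the background by
spectral angle, and inverted to per-pixel tissue parameters; tumor
regions come from the ground-truth masks (standing in for the expert
segmentation of a real study).  The 80-column feature table is built per
(subject, day, tissue class), the top features are selected by MRMR on
the training mice only, the 30-classifier registry is benchmarked with
subject-grouped cross-validation, and every family is scored on the
held-out validation mice.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classification import (
    ClassifierRegistry,
    EvalReport,
    load_default_registry,
    select_and_validate,
    train_eval_all,
)
from .cohort import Cohort, CohortDesign, TumorTrajectory, generate_cohort
from .features import FeatureConfig, FeatureTable, build_feature_table
from .inversion import FitBounds, ParameterMaps, default_cube_bounds, fit_cube
from .lut import build_default_lut
from .preprocessing import (
    LABEL_BACKGROUND,
    LABEL_HEALTHY,
    LABEL_TUMOR,
    TissueMask,
    normalize_reflectance,
    reduce_cube,
    remove_background,
)
from .selection import MrmrResult, mrmr_select

__all__ = ["Observation", "StudyResult", "invert_cohort", "run_study",
           "benchmark_observations"]


@dataclass
class Observation:
    """One inverted imaging session: fitted maps plus region labels."""

    subject: int
    day: float
    split: str
    maps: ParameterMaps
    mask: TissueMask


@dataclass
class StudyResult:
    cohort: Cohort
    observations: list
    table: FeatureTable
    selection: MrmrResult
    report: EvalReport
    validation: pd.DataFrame
    selected_columns: list

    @property
    def max_validation_auc(self) -> float:
        return float(np.nanmax(self.validation["auc"].to_numpy()))


def _segment(reduced, truth_mask):
    """Tissue mask from spectral angle, tumor labels from ground truth.

    The tissue mask is eroded by one pixel: after binning, boundary
    pixels are partial-volume mixtures of tissue and background and
    would bias the fitted maps.
    """
    from scipy.ndimage import binary_erosion
    sam = remove_background(reduced)
    tissue = binary_erosion(sam.tissue)
    labels = np.full(tissue.shape, LABEL_BACKGROUND, np.uint8)
    labels[tissue] = LABEL_HEALTHY
    tumor = truth_mask.tumor & tissue
    labels[tumor] = LABEL_TUMOR
    return TissueMask(tissue=tissue, labels=labels)


def invert_cohort(cohort: Cohort, bounds: FitBounds | None = None,
                  strategy: str = "lut", lut=None,
                  max_iter: int = 60) -> list:
    """Preprocess and fit every cohort image; returns Observations."""
    bounds = bounds or default_cube_bounds()
    if strategy == "lut" and lut is None:
        lut = build_default_lut(de=bounds.initial["de"])
    out = []
    for im in cohort.images:
        norm = normalize_reflectance(im.raw.data, im.dark, im.white,
                                     grid=im.raw.grid)
        reduced = reduce_cube(norm, spatial_bin=cohort.design.oversample)
        mask = _segment(reduced, im.truth_mask)
        maps = fit_cube(reduced, mask.tissue, grid=reduced.grid,
                        bounds=bounds, strategy=strategy, lut=lut,
                        max_iter=max_iter)
        out.append(Observation(subject=im.mouse, day=im.day, split=im.split,
                               maps=maps, mask=mask))
    return out


def _table_from_observations(observations, cfg: FeatureConfig):
    return build_feature_table(
        [dict(subject=o.subject, day=o.day, split=o.split,
              maps=o.maps, mask=o.mask) for o in observations], cfg)


def benchmark_observations(observations, registry=None, k: int = 10,
                           n_folds: int = 4, seed: int = 0,
                           cfg: FeatureConfig = FeatureConfig(),
                           table: FeatureTable | None = None):
    """Feature table -> MRMR (training rows only) -> grouped CV benchmark
    -> validation.  Returns (table, selection, report, validation,
    selected_columns)."""
    registry = registry or load_default_registry()
    table = table or _table_from_observations(observations, cfg)
    df = table.data
    train = df["split"] == "train"
    X = table.features
    y = table.labels
    subj = table.subjects
    sel = mrmr_select(X[train.to_numpy()], y[train.to_numpy()], k=k)
    cols = sorted(sel.ranked)
    Xs = X[:, cols]
    tr = train.to_numpy()
    report = train_eval_all(Xs[tr], y[tr], subj[tr], registry,
                            n_folds=n_folds, seed=seed)
    validation = select_and_validate(report, Xs[tr], y[tr], subj[tr],
                                     Xs[~tr], y[~tr], subj[~tr],
                                     registry, seed=seed)
    return table, sel, report, validation, cols


def run_study(seed: int = 0, design: CohortDesign | None = None,
              trajectory: TumorTrajectory | None = None,
              registry: ClassifierRegistry | None = None,
              k: int = 10, n_folds: int = 4,
              cfg: FeatureConfig = FeatureConfig(),
              cohort: Cohort | None = None,
              observations: list | None = None) -> StudyResult:
    """Run the whole study at one seed and collect every artifact."""
    cohort = cohort or generate_cohort(design=design, trajectory=trajectory,
                                       seed=seed)
    observations = observations or invert_cohort(cohort)
    table, sel, report, validation, cols = benchmark_observations(
        observations, registry=registry, k=k, n_folds=n_folds, seed=seed,
        cfg=cfg)
    return StudyResult(cohort=cohort, observations=observations, table=table,
                       selection=sel, report=report, validation=validation,
                       selected_columns=cols)
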