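"""Robustness protocols: smoothing sweep, leave-one-day-out, and
day-wise significance testing.

Both perturbation experiments re-run the downstream pipeline from the
fitted parameter maps: feature extraction, MRMR selection (training mice
only), grouped cross-validation over the classifier registry, and
validation on the held-out mice.  The smoothing sweep varies a Gaussian
kernel applied to the parameter maps before feature extraction; the
leave-one-day-out experiment drops one imaging day at a time from
feature selection and training (never from the validation mice).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classification import ClassifierRegistry, load_default_registry
from .features import FeatureConfig, build_feature_table, gaussian_smooth_maps
from .pipeline import Observation, benchmark_observations
from .selection import MrmrResult

__all__ = ["SweepResult", "smoothing_sweep", "leave_one_day_out",
           "daily_significance", "DEFAULT_SIGMAS"]

# 0 to 10 in steps of 0.5: 21 smoothing conditions
DEFAULT_SIGMAS = tuple(np.arange(0.0, 10.5, 0.5))


@dataclass
class SweepResult:
    """Per-condition outcomes of a robustness experiment.

    conditions : sigma values or omitted days
    selections : MrmrResult per condition
    validation : long DataFrame (condition, model, auc, f1, ...)
    """

    kind: str
    conditions: list
    selections: list
    validation: pd.DataFrame
    cv_reports: list = field(default_factory=list)

    def curve(self, metric: str = "auc") -> pd.DataFrame:
        """Best, worst and mean metric across models per condition."""
        g = self.validation.groupby("condition", sort=False)[metric]
        return pd.DataFrame({
            "condition": list(g.groups.keys()),
            "best": g.max().to_numpy(),
            "worst": g.min().to_numpy(),
            "mean": g.mean().to_numpy(),
        })

    def mean_metric(self, condition, metric: str = "auc") -> float:
        sel = self.validation[self.validation["condition"] == condition]
        return float(np.nanmean(sel[metric].to_numpy()))


def smoothing_sweep(observations, sigmas=DEFAULT_SIGMAS,
                    registry: ClassifierRegistry | None = None,
                    k: int = 10, n_folds: int = 4, seed: int = 0,
                    cfg: FeatureConfig = FeatureConfig()) -> SweepResult:
    """Re-run feature extraction, selection and the benchmark for each
    Gaussian smoothing level applied to the fitted parameter maps.

    sigma = 0 applies no smoothing, so its condition reproduces the
    baseline pipeline exactly (same seeds throughout).
    """
    registry = registry or load_default_registry()
    selections = []
    frames = []
    reports = []
    for sigma in sigmas:
        smoothed = [
            Observation(subject=o.subject, day=o.day, split=o.split,
                        maps=gaussian_smooth_maps(o.maps, float(sigma)),
                        mask=o.mask)
            for o in observations]
        _, sel, report, validation, _cols = benchmark_observations(
            smoothed, registry=registry, k=k, n_folds=n_folds, seed=seed,
            cfg=cfg)
        selections.append(sel)
        reports.append(report)
        v = validation.copy()
        v.insert(0, "condition", float(sigma))
        frames.append(v)
    return SweepResult(kind="smoothing", conditions=[float(s) for s in sigmas],
                       selections=selections,
                       validation=pd.concat(frames, ignore_index=True),
                       cv_reports=reports)


def leave_one_day_out(observations,
                      registry: ClassifierRegistry | None = None,
                      k: int = 10, n_folds: int = 4, seed: int = 0,
                      cfg: FeatureConfig = FeatureConfig()) -> SweepResult:
    """Drop one imaging day at a time from feature selection and
    training/testing; the validation mice keep all their rows.

    Day 0 (the injection day) is never omitted.  Rows of the omitted day
    never reach the MRMR input or a training fold.
    """
    registry = registry or load_default_registry()
    days = sorted({o.day for o in observations if o.day != 0})
    table = build_feature_table(
        [dict(subject=o.subject, day=o.day, split=o.split,
              maps=o.maps, mask=o.mask) for o in observations], cfg)
    selections = []
    frames = []
    reports = []
    from .classification import select_and_validate, train_eval_all
    from .selection import mrmr_select

    df = table.data
    X = table.features
    y = table.labels
    subj = table.subjects
    train = (df["split"] == "train").to_numpy()
    val = ~train
    for day in days:
        keep = train & (df["day"] != day).to_numpy()
        sel = mrmr_select(X[keep], y[keep], k=k)
        cols = sorted(sel.ranked)
        report = train_eval_all(X[np.ix_(keep, cols)], y[keep], subj[keep],
                                registry, n_folds=n_folds, seed=seed)
        validation = select_and_validate(
            report, X[np.ix_(keep, cols)], y[keep], subj[keep],
            X[np.ix_(val, cols)], y[val], subj[val], registry, seed=seed)
        selections.append(sel)
        reports.append(report)
        v = validation.copy()
        v.insert(0, "condition", day)
        frames.append(v)
    return SweepResult(kind="leave_one_day_out", conditions=days,
                       selections=selections,
                       validation=pd.concat(frames, ignore_index=True),
                       cv_reports=reports)


def daily_significance(values, days, classes, alpha: float = 0.05,
                       test: str = "welch") -> pd.DataFrame:
    """Two-sided per-day tumor-vs-healthy tests on a scalar quantity.

    values, days, classes : aligned 1-D arrays; classes are
    "tumor"/"healthy" strings or 1/0 labels.  test="welch" (unequal
    variance t) or "mannwhitney".  Returns a DataFrame with one row per
    day: p-value and a significance flag (p < alpha); days where either
    group is degenerate get a missing flag.
    """
    values = np.asarray(values, float)
    days_arr = np.asarray(days)
    cls = np.asarray(classes)
    if cls.dtype.kind in "SUO":
        is_tumor = cls == "tumor"
    else:
        is_tumor = cls.astype(int) == 1
    rows = []
    for day in sorted(set(days_arr.tolist())):
        sel = days_arr == day
        a = values[sel & is_tumor]
        b = values[sel & ~is_tumor]
        if a.size < 2 or b.size < 2 or (a.std() == 0 and b.std() == 0):
            rows.append(dict(day=day, p_value=np.nan, significant=None,
                             n_tumor=a.size, n_healthy=b.size))
            continue
        if test == "welch":
            p = stats.ttest_ind(a, b, equal_var=False).pvalue
        elif test == "mannwhitney":
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(dict(day=day, p_value=float(p),
                         significant=bool(p < alpha),
                         n_tumor=a.size, n_healthy=b.size))
    return pd.DataFrame(rows)
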