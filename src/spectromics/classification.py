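"""Tumor/healthy discrimination benchmark.

Thirty scikit-learn classifier families (the packaged registry) are
trained with default hyperparameters on the MRMR-selected features under
subject-grouped cross-validation: every fold tests on exactly one
subject, so no animal contributes to both training and testing.  The
best family by cross-validated AUC is refit on all train/test rows and
scored once on the held-out validation subjects.
"""
from __future__ import annotations

import importlib
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.metrics import (
    accuracy_score,
    balanced_accuracy_score,
    f1_score,
    precision_score,
    recall_score,
)
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import MinMaxScaler

__all__ = [
    "ClassifierRegistry",
    "EvalReport",
    "load_default_registry",
    "grouped_cv_split",
    "compute_metrics",
    "rank_auc",
    "train_eval_all",
    "select_and_validate",
    "ContaminationError",
]

METRIC_NAMES = ("accuracy", "balanced_accuracy", "precision", "recall",
                "f1", "auc")


class ContaminationError(ValueError):
    """A subject appears on both sides of a train/test or train/validation
    split."""


@dataclass
class ClassifierRegistry:
    """Named, seeded scikit-learn estimator factories (stable order)."""

    entries: list  # list of (name, factory) where factory(seed) -> estimator

    def __post_init__(self):
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("registry names must be unique")

    def __len__(self):
        return len(self.entries)

    @property
    def names(self):
        return [n for n, _ in self.entries]

    def build(self, seed: int):
        """Instantiate every entry with its seed fixed."""
        return [(name, factory(seed)) for name, factory in self.entries]

    def subset(self, names) -> "ClassifierRegistry":
        keep = set(names)
        return ClassifierRegistry(
            [(n, f) for n, f in self.entries if n in keep])


def _make_factory(cls_path: str, params: dict, scale: str | None):
    module, clsname = cls_path.rsplit(".", 1)
    est_cls = getattr(importlib.import_module(module), clsname)

    def factory(seed: int):
        kwargs = dict(params)
        if "random_state" in est_cls().get_params():
            kwargs.setdefault("random_state", seed)
        est = est_cls(**kwargs)
        if scale == "minmax":
            return make_pipeline(MinMaxScaler(), est)
        return est

    return factory


def load_default_registry() -> ClassifierRegistry:
    """The packaged 30-entry roster (config data, editable)."""
    ref = resources.files("spectromics.data").joinpath(
        "classifier_registry.yaml")
    spec = yaml.safe_load(ref.read_text())
    entries = []
    for e in spec["entries"]:
        entries.append((e["name"], _make_factory(e["cls"], e.get("params", {}),
                                                 e.get("scale"))))
    return ClassifierRegistry(entries)


def grouped_cv_split(subjects, n_folds: int = 4):
    """Leave-one-subject-out folds over the first ``n_folds`` subjects.

    Every fold's test set holds all rows of exactly one subject; rows of
    any remaining subjects always stay in training.  Returns a list of
    (train_idx, test_idx) pairs.
    """
    subjects = np.asarray(subjects)
    uniq = list(dict.fromkeys(subjects))  # stable order of appearance
    if len(uniq) < n_folds:
        raise ValueError(
            f"need >= {n_folds} distinct subjects, got {len(uniq)}")
    folds = []
    idx = np.arange(subjects.size)
    for s in uniq[:n_folds]:
        test = idx[subjects == s]
        train = idx[subjects != s]
        folds.append((train, test))
    return folds


def rank_auc(labels, scores) -> float:
    """AUC by the rank (Mann-Whitney) formulation, ties averaged."""
    y = np.asarray(labels)
    s = np.asarray(scores, float)
    npos = int((y == 1).sum())
    nneg = int((y == 0).sum())
    if npos == 0 or nneg == 0:
        return float("nan")
    r = rankdata(s)
    return float((r[y == 1].sum() - npos * (npos + 1) / 2) / (npos * nneg))


def compute_metrics(labels, predicted, scores=None) -> dict:
    """Standard binary metrics; tumor (1) is the positive class.

    AUC uses the rank formulation on ``scores``; with a single-class
    truth it is reported as NaN (undefined).
    """
    y = np.asarray(labels)
    yp = np.asarray(predicted)
    if y.size != yp.size:
        raise ValueError("labels and predictions must share a length")
    out = {
        "accuracy": accuracy_score(y, yp),
        "balanced_accuracy": balanced_accuracy_score(y, yp),
        "precision": precision_score(y, yp, zero_division=0),
        "recall": recall_score(y, yp, zero_division=0),
        "f1": f1_score(y, yp, zero_division=0),
    }
    out["auc"] = rank_auc(y, scores) if scores is not None else float("nan")
    return {k: float(v) for k, v in out.items()}


def _scores_of(model, X):
    if hasattr(model, "predict_proba"):
        try:
            return model.predict_proba(X)[:, -1]
        except Exception:  # pragma: no cover - proba can fail post-fit
            pass
    if hasattr(model, "decision_function"):
        try:
            return np.asarray(model.decision_function(X), float)
        except Exception:  # pragma: no cover
            pass
    return model.predict(X).astype(float)


@dataclass
class EvalReport:
    """Cross-validation benchmark results.

    per_fold : model x fold metric rows; summary : per-model mean/SD;
    warnings : (model, fold, message) for non-converged or failed fits.
    """

    per_fold: pd.DataFrame
    summary: pd.DataFrame
    warnings: list = field(default_factory=list)

    def mean_auc(self, model: str) -> float:
        row = self.summary[self.summary["model"] == model]
        return float(row["auc_mean"].iloc[0])

    @property
    def best_model(self) -> str:
        s = self.summary.sort_values(["auc_mean", "model"],
                                     ascending=[False, True])
        return str(s["model"].iloc[0])

    def to_json(self, path) -> None:
        import json
        with open(path, "w") as fh:
            json.dump({
                "per_fold": self.per_fold.to_dict(orient="records"),
                "summary": self.summary.to_dict(orient="records"),
                "warnings": [list(w) for w in self.warnings],
            }, fh, indent=1)

    def to_csv(self, path) -> None:
        """Flat per-model-per-fold metric table."""
        self.per_fold.to_csv(path, index=False)


def train_eval_all(X, y, subjects, registry: ClassifierRegistry | None = None,
                   n_folds: int = 4, seed: int = 0) -> EvalReport:
    """Train and evaluate every registry entry on subject-grouped folds."""
    registry = registry or load_default_registry()
    X = np.asarray(X, float)
    y = np.asarray(y)
    folds = grouped_cv_split(subjects, n_folds)
    rows = []
    warns = []
    models = registry.build(seed)
    for name, proto in models:
        for k, (tr, te) in enumerate(folds):
            model = clone(proto)
            metrics = {m: float("nan") for m in METRIC_NAMES}
            try:
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    model.fit(X[tr], y[tr])
                    pred = model.predict(X[te])
                    sc = _scores_of(model, X[te])
                for w in caught:
                    if "onverg" in str(w.message):
                        warns.append((name, k, str(w.message)))
                metrics = compute_metrics(y[te], pred, sc)
            except Exception as exc:
                warns.append((name, k, f"fit failed: {exc}"))
            rows.append(dict(model=name, fold=k, **metrics))
    per_fold = pd.DataFrame(rows)
    agg = per_fold.groupby("model", sort=False)
    summary = agg[list(METRIC_NAMES)].mean().add_suffix("_mean")
    summary = summary.join(agg[list(METRIC_NAMES)].std().add_suffix("_sd"))
    summary = summary.reset_index()
    return EvalReport(per_fold=per_fold, summary=summary, warnings=warns)


def select_and_validate(report: EvalReport, X_train, y_train, subj_train,
                        X_val, y_val, subj_val,
                        registry: ClassifierRegistry | None = None,
                        seed: int = 0) -> pd.DataFrame:
    """Refit every family on all train/test rows and score the held-out
    validation subjects; raises before any training if a subject leaks
    across the split.  Returns per-model validation metrics sorted with
    the report's model order; the report's ``best_model`` row is the
    headline result.
    """
    registry = registry or load_default_registry()
    overlap = set(np.asarray(subj_train)) & set(np.asarray(subj_val))
    if overlap:
        raise ContaminationError(
            f"subjects {sorted(overlap)} appear in both train and validation")
    X_train = np.asarray(X_train, float)
    X_val = np.asarray(X_val, float)
    rows = []
    for name, model in registry.build(seed):
        metrics = {m: float("nan") for m in METRIC_NAMES}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X_train, y_train)
                pred = model.predict(X_val)
                sc = _scores_of(model, X_val)
            metrics = compute_metrics(y_val, pred, sc)
        except Exception:
            pass
        rows.append(dict(model=name, **metrics))
    return pd.DataFrame(rows)
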