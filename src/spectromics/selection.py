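"""Max-Relevance Min-Redundancy feature ranking.

Greedy forward selection maximizing Phi = D - R, where D is the mutual
information of a candidate feature with the class label and R is its mean
mutual information with the already selected features (the difference
form of the criterion).  Mutual information is the plug-in estimate on
quantile-discretized features, which is robust at the small sample sizes
of the cohort and invariant to monotone feature transformations.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MrmrResult", "mutual_information", "mrmr_select",
           "cumulative_importance", "discretize"]


def discretize(x, bins: int = 4) -> np.ndarray:
    """Quantile discretization to at most ``bins`` levels."""
    x = np.asarray(x, float)
    if np.unique(x).size <= bins:
        _, inv = np.unique(x, return_inverse=True)
        return inv
    edges = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def mutual_information(x, y, bins: int = 4) -> float:
    """Mutual information in bits between two columns.

    Continuous inputs are quantile-discretized; already-discrete inputs
    (few unique values) are used as-is.  Symmetric and non-negative;
    a constant column gives 0.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size != y.size:
        raise ValueError("columns must share a length")
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    xi = discretize(x, bins)
    yi = discretize(y, bins)
    nx = int(xi.max()) + 1
    ny = int(yi.max()) + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).astype(float)
    joint = joint.reshape(nx, ny) / x.size
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nzi, nzj = np.nonzero(joint)
    p = joint[nzi, nzj]
    return float(np.maximum(
        (p * np.log2(p / (px[nzi] * py[nzj]))).sum(), 0.0))


@dataclass
class MrmrResult:
    """Ranked selection with per-step criterion values.

    ranked : 0-based column indices in selection order
    phi : criterion value Phi = D - R at each selection step
    relevance : D (MI with the label) per selected feature
    redundancy : R (mean MI with previously selected) per selected feature
    """

    ranked: list
    phi: list
    relevance: list
    redundancy: list
    n_features: int = 0

    def scores_vector(self) -> np.ndarray:
        """Phi scores scattered over all feature columns (0 if unselected)."""
        v = np.zeros(self.n_features)
        for idx, s in zip(self.ranked, self.phi):
            v[idx] = s
        return v

    def as_dict(self, names=None, config=None) -> dict:
        """JSON-ready report: ranked indices, names, Phi, D, R, config."""
        d = {
            "ranked": [int(i) for i in self.ranked],
            "phi": [float(v) for v in self.phi],
            "relevance": [float(v) for v in self.relevance],
            "redundancy": [float(v) for v in self.redundancy],
            "n_features": int(self.n_features),
        }
        if names is not None:
            d["names"] = [str(names[i]) for i in self.ranked]
        if config is not None:
            d["config"] = config
        return d

    def to_json(self, path, names=None, config=None) -> None:
        import json
        with open(path, "w") as fh:
            json.dump(self.as_dict(names=names, config=config), fh, indent=1)


def mrmr_select(table, labels, k: int = 10, bins: int = 4) -> MrmrResult:
    """Greedy MRMR ranking of ``k`` features against binary labels.

    table : (n, p) array or FeatureTable.  The first feature maximizes
    relevance alone; each next feature maximizes relevance minus mean
    redundancy with the selected set.  Ties break to the lowest column
    index (argmax convention), making the ranking deterministic.
    Constant columns carry no information and are never selected (their
    Phi of exactly zero would otherwise beat informative-but-redundant
    candidates with negative Phi).
    """
    X = np.asarray(getattr(table, "features", table), float)
    y = np.asarray(labels)
    n, p = X.shape
    if not 1 <= k <= p:
        raise ValueError("k must be in 1..n_features")
    if np.unique(y).size < 2:
        raise ValueError("labels must contain both classes")
    col_const = np.all(X == X[0], axis=0)
    if col_const.all():
        raise ValueError("all features are constant")
    if (~col_const).sum() < k:
        raise ValueError(
            f"only {(~col_const).sum()} non-constant features for k={k}")

    relevance = np.array([mutual_information(X[:, j], y, bins)
                          for j in range(p)])
    selected: list[int] = []
    phis: list[float] = []
    rels: list[float] = []
    reds: list[float] = []
    red_cache = np.zeros((0, p))
    for _ in range(k):
        if selected:
            mean_red = red_cache.mean(axis=0)
        else:
            mean_red = np.zeros(p)
        phi = relevance - mean_red
        phi[selected] = -np.inf
        phi[col_const] = -np.inf
        j = int(np.argmax(phi))
        selected.append(j)
        phis.append(float(phi[j]))
        rels.append(float(relevance[j]))
        reds.append(float(mean_red[j]))
        mi_row = np.array([mutual_information(X[:, j], X[:, m], bins)
                           for m in range(p)])
        red_cache = np.vstack([red_cache, mi_row])
    return MrmrResult(ranked=selected, phi=phis, relevance=rels,
                      redundancy=reds, n_features=p)


def cumulative_importance(results) -> np.ndarray:
    """Sum of Phi scores per feature over repeated selections.

    Used to pool rankings across experimental repetitions (smoothing
    levels, leave-one-day-out folds); features never selected score 0.
    """
    results = list(results)
    if not results:
        raise ValueError("need at least one MRMR result")
    p = results[0].n_features
    if any(r.n_features != p for r in results):
        raise ValueError("results disagree on the feature count")
    return np.sum([r.scores_vector() for r in results], axis=0)
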