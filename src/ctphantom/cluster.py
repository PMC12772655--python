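"""PCA embedding of radiomics features and cluster-consistency statistics.

Features are z-score standardized, projected onto the principal components
retaining 95% of total variance, and lesion-type clusters (solid,
part-solid, ground-glass; sizes, doses and repetitions pooled) are
summarized by

* within-cluster distance - mean Euclidean distance of a cluster's points
  to their centroid (feature-consistency across acquisition conditions),
* separability - mean pairwise centroid distance divided by the mean
  within-cluster distance (lesion-type discrimination).

The PCA space is fitted jointly on all scanners; per-scanner statistics
are computed on that scanner's points inside the joint space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from itertools import combinations
from sklearn.decomposition import PCA

__all__ = [
    "PcSpace",
    "ClusterReport",
    "fit_pca",
    "project",
    "within_cluster_distance",
    "separability",
    "nearest_centroid_accuracy",
]


@dataclass
class PcSpace:
    """A fitted standardize-then-rotate embedding."""

    feature_names: tuple[str, ...]
    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray  # (n_components, n_features) rows = loadings
    explained_variance_ratio: np.ndarray
    n_retained: int  # components reaching the variance threshold
    variance_threshold: float
    dropped: tuple[str, ...] = ()

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale


def _as_matrix(features, feature_names=None):
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), tuple(features.columns)
    X = np.asarray(features, dtype=float)
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"f{i}" for i in range(X.shape[1])
    )
    return X, names


def fit_pca(
    features,
    feature_names=None,
    variance_threshold: float = 0.95,
    standardize: bool = True,
) -> PcSpace:
    """Fit the joint PC space on a (measurements x features) table.

    Constant features are dropped with a warning.  Component signs follow a
    deterministic convention: the largest-magnitude loading of each
    component is positive.
    """
    X, names = _as_matrix(features, feature_names)
    if X.shape[0] < 2:
        raise ValueError("need at least two measurements to fit a PC space")
    sd = X.std(axis=0)
    keep = sd > 0
    dropped = tuple(n for n, k in zip(names, keep) if not k)
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant feature(s): {dropped[:5]}...")
    X = X[:, keep]
    names = tuple(n for n, k in zip(names, keep) if k)
    mean = X.mean(axis=0)
    scale = X.std(axis=0) if standardize else np.ones(X.shape[1])
    Z = (X - mean) / scale

    pca = PCA(svd_solver="full")
    pca.fit(Z)
    comps = pca.components_.copy()
    for row in comps:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    m = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    m = min(m, len(evr))
    return PcSpace(
        feature_names=names,
        mean=mean,
        scale=scale,
        components=comps,
        explained_variance_ratio=evr,
        n_retained=m,
        variance_threshold=variance_threshold,
        dropped=dropped,
    )


def project(features, space: PcSpace, n_components: int | None = None) -> np.ndarray:
    """Project measurements into the first ``n_components`` (default: the
    95%-variance count) of a fitted space.  Feature names must match the fit."""
    if isinstance(features, pd.DataFrame):
        missing = [n for n in space.feature_names if n not in features.columns]
        if missing:
            raise ValueError(f"missing features: {missing[:5]}...")
        X = features.loc[:, list(space.feature_names)].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.shape[1] != len(space.feature_names):
            raise ValueError(
                f"expected {len(space.feature_names)} features, got {X.shape[1]}"
            )
    m = space.n_retained if n_components is None else n_components
    Z = space.standardize(X)
    return Z @ space.components[:m].T


def within_cluster_distance(
    points: np.ndarray, cluster_labels
) -> dict[object, tuple[float, float]]:
    """Per-cluster (mean, SD) of point-to-centroid Euclidean distances."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(cluster_labels)
    if points.shape[0] != labels.shape[0]:
        raise ValueError("points and labels differ in length")
    out = {}
    for lab in pd.unique(labels):
        sub = points[labels == lab]
        if sub.shape[0] == 0:
            raise ValueError(f"empty cluster {lab!r}")
        centroid = sub.mean(axis=0)
        d = np.linalg.norm(sub - centroid, axis=1)
        out[lab] = (float(d.mean()), float(d.std(ddof=0)))
    return out


def separability(points: np.ndarray, cluster_labels) -> float:
    """Mean pairwise centroid distance over mean within-cluster distance."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(cluster_labels)
    uniq = list(pd.unique(labels))
    if len(uniq) < 2:
        raise ValueError("need at least two clusters")
    centroids = {lab: points[labels == lab].mean(axis=0) for lab in uniq}
    within = within_cluster_distance(points, labels)
    mean_within = float(np.mean([within[lab][0] for lab in uniq]))
    pair_d = [
        float(np.linalg.norm(centroids[a] - centroids[b]))
        for a, b in combinations(uniq, 2)
    ]
    mean_between = float(np.mean(pair_d))
    if mean_within == 0:
        warnings.warn("all clusters degenerate: separability is infinite")
        return float("inf")
    return mean_between / mean_within


def nearest_centroid_accuracy(points: np.ndarray, cluster_labels) -> float:
    """Fraction of points whose nearest cluster centroid carries their own
    label (a label-recovery check of the embedding)."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(cluster_labels)
    uniq = list(pd.unique(labels))
    centroids = np.stack([points[labels == lab].mean(axis=0) for lab in uniq])
    d = np.linalg.norm(points[:, None, :] - centroids[None, :, :], axis=2)
    assigned = np.asarray(uniq, dtype=object)[np.argmin(d, axis=1)]
    return float((assigned == labels.astype(object)).mean())


@dataclass
class ClusterReport:
    """Per-scanner within-cluster distances and separability."""

    n_components: int
    explained_variance_ratio: tuple[float, ...]
    within: dict[str, dict[str, tuple[float, float]]]  # scanner -> type -> (mean, sd)
    separability: dict[str, float]  # scanner -> value

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "explained_variance_ratio": list(self.explained_variance_ratio),
            "within_cluster_distance": {
                sc: {t: {"mean": m, "sd": s} for t, (m, s) in d.items()}
                for sc, d in self.within.items()
            },
            "separability": dict(self.separability),
        }
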