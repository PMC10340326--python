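"""Lloyd k-means and 2-D projections for visual cluster analysis.

The clustering follows the classical recipe: k distinct data points drawn at
random become the initial centers, samples are assigned to their nearest
center by squared Euclidean distance, centers are recentered at cluster
means, and the loop repeats until the centers stop moving.  Initialization
is plain random-point draw (not k-means++), with the seed exposed.  An
emptied cluster is re-seeded from the point farthest from its assigned
center.

For visualization, high-dimensional samples are projected to 2-D either by
(per-sample mean, per-sample population STD) or by picking two feature
columns (a seeded random distinct pair when none is given).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .errors import ParameterError

logger = logging.getLogger(__name__)


@dataclass
class KMeansResult:
    centers: np.ndarray
    assignment: np.ndarray
    inertia: float
    iterations: int
    inertia_history: list[float]


def _inertia(points: np.ndarray, centers: np.ndarray, assignment: np.ndarray) -> float:
    return float(np.sum((points - centers[assignment]) ** 2))


def _assign(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def kmeans(
    points,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> KMeansResult:
    """Lloyd iterations from k random distinct starting points.

    Stops when every center moves less than ``tol`` (Euclidean) or after
    ``max_iter`` iterations.  Inertia is non-increasing across iterations
    and the result is a Lloyd fixed point up to ``tol``.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    distinct = np.unique(points, axis=0)
    if k < 1 or k > distinct.shape[0]:
        raise ParameterError(
            f"k={k} must be between 1 and the number of distinct points ({distinct.shape[0]})"
        )
    rng = np.random.default_rng(seed)
    centers = distinct[rng.choice(distinct.shape[0], size=k, replace=False)].copy()

    assignment = _assign(points, centers)
    history = [_inertia(points, centers, assignment)]
    iterations = 0
    for _ in range(max_iter):
        iterations += 1
        new_centers = centers.copy()
        for j in range(k):
            members = points[assignment == j]
            if members.shape[0] == 0:
                far = np.argmax(((points - centers[assignment]) ** 2).sum(axis=1))
                new_centers[j] = points[far]
            else:
                new_centers[j] = members.mean(axis=0)
        shift = np.sqrt(((new_centers - centers) ** 2).sum(axis=1)).max()
        centers = new_centers
        assignment = _assign(points, centers)
        history.append(_inertia(points, centers, assignment))
        if shift < tol:
            break
    return KMeansResult(centers, assignment, history[-1], iterations, history)


class SpectrumKMeans(BaseEstimator, ClusterMixin):
    """Estimator wrapper around :func:`kmeans` (random-point init Lloyd).

    Attributes after fit: ``cluster_centers_``, ``labels_``, ``inertia_``,
    ``n_iter_``.
    """

    def __init__(self, n_clusters: int = 2, seed: int = 0, max_iter: int = 300, tol: float = 1e-9):
        self.n_clusters = n_clusters
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        res = kmeans(X, self.n_clusters, seed=self.seed, max_iter=self.max_iter, tol=self.tol)
        self.cluster_centers_ = res.centers
        self.labels_ = res.assignment
        self.inertia_ = res.inertia
        self.n_iter_ = res.iterations
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return _assign(X, self.cluster_centers_)


@dataclass
class Projection2D:
    """One (x, y) point per sample plus axis labels."""

    x: np.ndarray
    y: np.ndarray
    x_label: str
    y_label: str

    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


def mean_std_projection(feature_matrix) -> Projection2D:
    """x = per-sample mean, y = per-sample population STD (divisor n)."""
    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ParameterError("each sample needs >= 2 features for a mean/STD projection")
    return Projection2D(X.mean(axis=1), X.std(axis=1, ddof=0), "Mean", "STD")


def feature_pair_projection(
    feature_matrix, i: int | None = None, j: int | None = None, seed: int = 0
) -> Projection2D:
    """x = feature i, y = feature j.  When indices are omitted a seeded
    random distinct pair is drawn and logged."""
    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ParameterError("need >= 2 feature columns")
    if (i is None) != (j is None):
        raise ParameterError("supply both feature indices or neither")
    if i is None:
        rng = np.random.default_rng(seed)
        i, j = (int(v) for v in rng.choice(X.shape[1], size=2, replace=False))
        logger.info("feature_pair_projection: random pair (%d, %d) from seed %d", i, j, seed)
    if i == j:
        raise ParameterError("feature indices must differ")
    for idx in (i, j):
        if not (0 <= idx < X.shape[1]):
            raise ParameterError(f"feature index {idx} out of range [0, {X.shape[1]})")
    return Projection2D(X[:, i].copy(), X[:, j].copy(), f"feature_{i}", f"feature_{j}")


def write_projection_csv(
    path: str | Path,
    projection: Projection2D,
    sample_ids,
    cluster=None,
    labels=None,
) -> None:
    """Point table: sample_id, x, y, cluster, label."""
    df = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            projection.x_label.lower(): projection.x,
            projection.y_label.lower(): projection.y,
        }
    )
    if cluster is not None:
        df["cluster"] = np.asarray(cluster)
    if labels is not None:
        df["label"] = list(labels)
    df.to_csv(Path(path), index=False)
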