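"""k-means clustering of habituation curves and the habituation space.

Normalized intensity curves are clustered with squared-Euclidean k-means
(k = 3 on the study data).  The three centroid curves are labelled
low / mid / high habituation by their terminal intensity, and every curve
is then summarised by its city-block (Manhattan) distance to each labelled
centroid.  The per-odorant medians of these three distances embed the
odorants in a 3-D *habituation space*: a large distance to a centroid means
low similarity to that habituation profile.

The k-means solver here is self-contained (Lloyd iterations with k-means++
seeding and restarts); scikit-learn's implementation serves only as an
independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_score

from .curves import CurveSet

__all__ = [
    "CurveKMeans",
    "CentroidSet",
    "kmeans_curves",
    "silhouette_profile",
    "label_centroids",
    "cityblock_to_centroids",
    "build_habituation_space",
]

HAB_LABELS = ["low_hab", "mid_hab", "high_hab"]


class CurveKMeans(ClusterMixin, BaseEstimator):
    """Squared-Euclidean k-means for equal-length curves.

    Lloyd's algorithm with k-means++ seeding, restarted ``n_init`` times and
    keeping the solution with the lowest within-cluster sum of squares.
    Deterministic for a fixed ``random_state``.

    Attributes
    ----------
    cluster_centers_ : ndarray (n_clusters, n_samples)
    labels_ : ndarray (n_curves,)
    inertia_ : float
        Within-cluster sum of squared distances of the best restart.
    """

    def __init__(self, n_clusters: int = 3, n_init: int = 50, max_iter: int = 300,
                 tol: float = 1e-8, random_state: int = 1):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_curves, n_samples)")
        n = X.shape[0]
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if n < self.n_clusters:
            raise ValueError(f"{n} curves cannot form {self.n_clusters} clusters")
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_init):
            centers, labels, inertia = self._lloyd(X, rng)
            if best is None or inertia < best[2]:
                best = (centers, labels, inertia)
        self.cluster_centers_, self.labels_, self.inertia_ = best
        return self

    def _plus_plus_init(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        n = X.shape[0]
        centers = [X[rng.integers(n)]]
        for _ in range(1, self.n_clusters):
            d2 = cdist(X, np.asarray(centers), "sqeuclidean").min(axis=1)
            total = d2.sum()
            if total <= 0:
                centers.append(X[rng.integers(n)])
                continue
            centers.append(X[rng.choice(n, p=d2 / total)])
        return np.asarray(centers)

    def _lloyd(self, X: np.ndarray, rng: np.random.Generator):
        centers = self._plus_plus_init(X, rng)
        labels = np.zeros(X.shape[0], dtype=int)
        inertia = np.inf
        for _ in range(self.max_iter):
            d2 = cdist(X, centers, "sqeuclidean")
            labels = d2.argmin(axis=1)
            new_inertia = d2[np.arange(X.shape[0]), labels].sum()
            for k in range(self.n_clusters):
                members = labels == k
                if members.any():
                    centers[k] = X[members].mean(axis=0)
                else:  # re-seed an empty cluster at the worst-fit point
                    centers[k] = X[d2.min(axis=1).argmax()]
            if inertia - new_inertia <= self.tol * max(inertia, 1.0):
                inertia = new_inertia
                break
            inertia = new_inertia
        d2 = cdist(X, centers, "sqeuclidean")
        labels = d2.argmin(axis=1)
        inertia = d2[np.arange(X.shape[0]), labels].sum()
        return centers, labels, inertia

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return cdist(X, self.cluster_centers_, "sqeuclidean").argmin(axis=1)


@dataclass
class CentroidSet:
    """k centroid curves with assignments and optional habituation labels."""

    centroids: np.ndarray          # (k, n_samples)
    assignment: np.ndarray         # (n_curves,)
    inertia: float
    times: np.ndarray
    labels: dict | None = None     # centroid index -> low/mid/high_hab
    mean_silhouette: float | None = None

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def labelled_centroid(self, name: str) -> np.ndarray:
        if self.labels is None:
            raise ValueError("centroids are not labelled yet")
        inv = {v: i for i, v in self.labels.items()}
        return self.centroids[inv[name]]


def kmeans_curves(curves, k: int, n_restarts: int = 50, seed: int = 1) -> CentroidSet:
    """Cluster curves (CurveSet or matrix) into k centroid curves."""
    X, times = _as_matrix(curves)
    km = CurveKMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
    return CentroidSet(
        centroids=km.cluster_centers_,
        assignment=km.labels_,
        inertia=km.inertia_,
        times=times,
    )


def _as_matrix(curves) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(curves, CurveSet):
        return curves.values, curves.times
    X = np.asarray(curves, dtype=float)
    return X, np.arange(X.shape[1], dtype=float)


def silhouette_profile(curves, k_range, n_restarts: int = 50, seed: int = 1) -> dict[int, float]:
    """Mean silhouette per candidate k (Euclidean distance on curve space)."""
    X, _ = _as_matrix(curves)
    out: dict[int, float] = {}
    for k in k_range:
        if not 2 <= k <= X.shape[0] - 1:
            raise ValueError(f"k={k} outside the admissible range [2, n-1]")
        cs = kmeans_curves(X, k, n_restarts=n_restarts, seed=seed)
        out[k] = float(silhouette_score(X, cs.assignment, metric="euclidean"))
    return out


def label_centroids(cs: CentroidSet, terminal_window_s: float = 30.0) -> CentroidSet:
    """Order the 3 centroids into low / mid / high habituation.

    The centroid with the highest mean intensity over the final
    ``terminal_window_s`` seconds habituated least (low_hab); the lowest is
    high_hab.  Ties fall back to total area under the curve; an exact tie
    is refused.
    """
    if cs.k != 3:
        raise ValueError("habituation labelling requires exactly 3 centroids")
    t_cut = cs.times[-1] - terminal_window_s
    tail = cs.times >= t_cut
    terminal = cs.centroids[:, tail].mean(axis=1)
    order = np.argsort(-terminal, kind="stable")
    if np.unique(terminal.round(12)).size < 3:
        auc = np.trapezoid(cs.centroids, cs.times, axis=1)
        keys = list(zip(-terminal.round(12), -auc.round(12)))
        if len(set(keys)) < 3:
            raise ValueError("centroids tie on terminal intensity and area")
        order = np.array(sorted(range(3), key=lambda i: keys[i]))
    labels = {int(order[i]): HAB_LABELS[i] for i in range(3)}
    return CentroidSet(
        centroids=cs.centroids,
        assignment=cs.assignment,
        inertia=cs.inertia,
        times=cs.times,
        labels=labels,
        mean_silhouette=cs.mean_silhouette,
    )


def cityblock_to_centroids(curves, cs: CentroidSet) -> pd.DataFrame:
    """City-block distance of every curve to each labelled centroid.

    d(curve, centroid) = sum_t |I(t) - C(t)| over the shared grid.  Returns
    one row per curve with columns d_low, d_mid, d_high (plus identifiers
    when a CurveSet is given).
    """
    if cs.labels is None:
        raise ValueError("centroids must be labelled before computing distances")
    X, _ = _as_matrix(curves)
    if X.shape[1] != cs.centroids.shape[1]:
        raise ValueError("curve length does not match centroid length")
    ordered = np.vstack([cs.labelled_centroid(name) for name in HAB_LABELS])
    dist = cdist(X, ordered, "cityblock")
    table = pd.DataFrame(dist, columns=["d_low", "d_mid", "d_high"])
    if isinstance(curves, CurveSet):
        table.insert(0, "odorant_id", curves.index["odorant_id"].to_numpy())
        table.insert(0, "subject_id", curves.index["subject_id"].to_numpy())
    return table


def build_habituation_space(distances: pd.DataFrame) -> pd.DataFrame:
    """Median of each distance coordinate per odorant (the regression Y).

    Odorants with no retained curves are absent from the result (a warning
    is emitted upstream when that happens).  Larger coordinates mean lower
    similarity to the corresponding habituation profile.
    """
    required = {"odorant_id", "d_low", "d_mid", "d_high"}
    missing = required - set(distances.columns)
    if missing:
        raise ValueError(f"distance table missing columns: {sorted(missing)}")
    space = distances.groupby("odorant_id")[["d_low", "d_mid", "d_high"]].median()
    return space.rename(columns={"d_low": "lowhab", "d_mid": "midhab", "d_high": "highhab"})
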