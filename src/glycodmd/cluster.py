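"""Single-cell trajectory classification from DMD amplitude features.

Per-cell mode-amplitude features are standardized, embedded with kernel
PCA (radial-basis kernel, bandwidth set by the median pairwise distance
heuristic) and clustered with k-means on the first three principal
components.  The cluster count can be fixed (the reference pipeline uses
four) or chosen by the silhouette criterion.  Cluster labels are
canonicalized by descending cluster size, so label 1 is always the largest
cluster and repeated runs under one seed are reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.decomposition import KernelPCA
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import StandardScaler

__all__ = [
    "ClusterReport",
    "kernel_pca_embed",
    "choose_k_silhouette",
    "kmeans_assign",
    "composition_table",
    "map_clusters_to_centroids",
    "classify_amplitudes",
]


@dataclass
class ClusterReport:
    pc_coords: np.ndarray          # (cells, 3)
    labels: np.ndarray             # (cells,) int, in 1..k
    k: int
    silhouette: dict               # candidate k -> mean silhouette
    composition: pd.DataFrame      # cluster x condition percentages
    seed: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min() < 1 or self.labels.max() > self.k:
            raise ValueError("labels must lie in 1..k")
        sums = self.composition.sum(axis=1).to_numpy()
        if not np.allclose(sums, 100.0, atol=0.1):
            raise ValueError("composition rows must sum to 100%")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "k": self.k,
            "seed": self.seed,
            "labels": self.labels.tolist(),
            "pc_coords": np.asarray(self.pc_coords).tolist(),
            "silhouette": {str(k): v for k, v in self.silhouette.items()},
            "composition": json.loads(self.composition.to_json()),
            "meta": self.meta,
        }
        text = json.dumps(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def kernel_pca_embed(features: np.ndarray, n_components: int = 3,
                     kernel: str = "rbf") -> np.ndarray:
    """Kernel-PCA coordinates of standardized amplitude features.

    Features are standardized per mode (zero mean, unit variance) so no
    single dominant mode dictates the kernel geometry.  The radial-basis
    bandwidth follows the median pairwise distance heuristic; a linear
    kernel (equivalent to ordinary PCA up to sign) is available for
    testing.  Deterministic up to per-component sign.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or not np.isfinite(X).all():
        raise ValueError("features must be a finite 2-D matrix")
    if X.shape[0] < n_components + 1:
        raise ValueError(
            f"need at least {n_components + 1} cells for "
            f"{n_components} components")
    X = StandardScaler().fit_transform(X)
    if kernel == "rbf":
        med = np.median(pdist(X))
        if med == 0:
            raise ValueError("degenerate kernel: all feature rows identical")
        kpca = KernelPCA(n_components=n_components, kernel="rbf",
                         gamma=1.0 / (2.0 * med ** 2))
    elif kernel == "linear":
        kpca = KernelPCA(n_components=n_components, kernel="linear")
    else:
        raise ValueError(f"unsupported kernel {kernel!r}")
    coords = kpca.fit_transform(X)
    if not np.isfinite(coords).all():
        raise ValueError("degenerate kernel decomposition")
    return coords


def choose_k_silhouette(pc_coords: np.ndarray, k_range=range(2, 9),
                        seed: int = 0) -> tuple[int, dict]:
    """Cluster count maximizing the mean silhouette; ties -> smallest k."""
    X = np.asarray(pc_coords, dtype=float)
    scores: dict[int, float] = {}
    for k in k_range:
        if k >= X.shape[0]:
            warnings.warn(f"skipping k = {k}: only {X.shape[0]} points",
                          UserWarning, stacklevel=2)
            continue
        labels = _run_kmeans(X, k, seed)
        if len(np.unique(labels)) < 2:
            continue
        scores[k] = float(silhouette_score(X, labels))
    if not scores:
        raise ValueError("no feasible cluster count in k_range")
    best = max(scores.values())
    k_best = min(k for k, v in scores.items() if np.isclose(v, best))
    return k_best, scores


def _run_kmeans(X: np.ndarray, k: int, seed: int) -> np.ndarray:
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(X)


def kmeans_assign(pc_coords: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Seeded k-means labels, canonically relabeled by descending size.

    Labels are 1-based; label 1 is the largest cluster.  Ties in size are
    broken by the smallest original member index for determinism.
    """
    X = np.asarray(pc_coords, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError(f"k = {k} exceeds {X.shape[0]} points")
    if k == 1:
        return np.ones(X.shape[0], dtype=int)
    raw = _run_kmeans(X, k, seed)
    sizes = np.bincount(raw, minlength=k)
    first = np.array([np.argmax(raw == c) if sizes[c] else X.shape[0]
                      for c in range(k)])
    order = np.lexsort((first, -sizes))
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return relabel[raw]


def composition_table(labels, conditions) -> pd.DataFrame:
    """Cluster-by-condition percentage table; every row sums to 100."""
    labels = np.asarray(labels, dtype=int)
    conditions = np.asarray(conditions)
    if labels.size != conditions.size:
        raise ValueError("labels and conditions must have equal length")
    table = pd.crosstab(pd.Series(labels, name="cluster"),
                        pd.Series(conditions, name="condition"))
    expected = set(range(1, labels.max() + 1))
    missing = expected - set(table.index)
    if missing:
        warnings.warn(f"empty cluster(s) omitted: {sorted(missing)}",
                      UserWarning, stacklevel=2)
    return table.div(table.sum(axis=1), axis=0) * 100.0


def map_clusters_to_centroids(labels, centroids) -> pd.DataFrame:
    """Join labels with per-cell centroid coordinates for mask overlays."""
    labels = np.asarray(labels, dtype=int)
    centroids = np.asarray(centroids, dtype=float)
    if centroids.shape != (labels.size, 2):
        raise ValueError("need one (x, y) centroid per labeled cell")
    return pd.DataFrame({"x": centroids[:, 0], "y": centroids[:, 1],
                         "cluster": labels})


def classify_amplitudes(features: np.ndarray, conditions,
                        k: int | None = None, seed: int = 0,
                        kernel: str = "rbf") -> ClusterReport:
    """Full amplitude -> kernel-PCA -> k-means pipeline.

    ``k = None`` selects the cluster count by the silhouette criterion
    over k = 2..8; a fixed ``k`` reproduces the reference four-cluster
    setting.
    """
    coords = kernel_pca_embed(features, n_components=3, kernel=kernel)
    if k is None:
        k_use, scores = choose_k_silhouette(coords, seed=seed)
    else:
        k_use = k
        _, scores = choose_k_silhouette(
            coords, k_range=range(2, max(9, k + 1)), seed=seed)
    labels = kmeans_assign(coords, k_use, seed=seed)
    comp = composition_table(labels, conditions)
    return ClusterReport(pc_coords=coords, labels=labels, k=k_use,
                         silhouette=scores, composition=comp, seed=seed)
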