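"""State identification: k-means on the embedded patterns plus model
selection of the number of states by elbow, silhouette and gap statistic.

k-means (Lloyd iterations, best of ``n_init`` seeded restarts by
within-cluster sum of squares) and the silhouette are delegated to
scikit-learn; the gap statistic and knee detection are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from ._utils import as_rng, knee_point

__all__ = [
    "ClusterModel",
    "KSelectionReport",
    "kmeans",
    "elbow_curve",
    "silhouette",
    "gap_statistic",
    "k_selection_report",
]


@dataclass
class ClusterModel:
    labels: np.ndarray
    centroids: np.ndarray
    wcss: float  # within-cluster sum of squares
    k: int
    seed: int
    n_init: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min() < 0 or self.labels.max() >= self.k:
            raise ValueError("labels out of range")
        if len(np.unique(self.labels)) != self.k:
            raise ValueError("every cluster must be non-empty")
        if self.wcss < 0:
            raise ValueError("wcss must be nonnegative")


@dataclass
class KSelectionReport:
    k_range: list[int]
    wcss: list[float]
    mean_silhouette: list[float]
    gap: list[float]
    gap_se: list[float]
    recommended: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "k_range": list(self.k_range),
            "wcss": [float(w) for w in self.wcss],
            "mean_silhouette": [float(s) for s in self.mean_silhouette],
            "gap": [float(g) for g in self.gap],
            "gap_se": [float(g) for g in self.gap_se],
            "recommended": dict(self.recommended),
        }


def kmeans(
    coords: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 50,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> ClusterModel:
    """k-means with k-means++ seeding, best of ``n_init`` restarts by WCSS.

    Deterministic given ``seed``. scikit-learn re-seeds any cluster emptied
    during Lloyd iterations from the points farthest from their centroids.
    """
    coords = np.asarray(coords, dtype=float)
    if k > coords.shape[0]:
        raise ValueError("k cannot exceed the number of points")
    km = KMeans(
        n_clusters=k,
        n_init=n_init,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
        init="k-means++",
    ).fit(coords)
    return ClusterModel(
        labels=km.labels_,
        centroids=km.cluster_centers_,
        wcss=float(km.inertia_),
        k=k,
        seed=seed,
        n_init=n_init,
    )


def elbow_curve(
    coords: np.ndarray,
    k_range,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[list[float], int]:
    """WCSS for each k in ``k_range`` and the knee k (max distance to chord).

    With a shared seed and enough restarts the curve is non-increasing in k.
    """
    k_range = sorted(int(k) for k in k_range)
    wcss = [kmeans(coords, k, seed=seed, n_init=n_init).wcss for k in k_range]
    if len(k_range) >= 2:
        knee_k = k_range[knee_point(np.array(k_range, float), np.array(wcss))]
    else:
        knee_k = k_range[0]
    return wcss, knee_k


def silhouette(coords: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-point silhouettes s(i) = (b - a) / max(a, b) and their mean.

    ``a`` is the mean distance to the point's own cluster, ``b`` the smallest
    mean distance to another cluster; singleton clusters score 0.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    s = silhouette_samples(np.asarray(coords, dtype=float), labels)
    return s, float(s.mean())


def gap_statistic(
    coords: np.ndarray,
    k_range,
    n_refs: int = 50,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Gap statistic over ``k_range`` with a uniform bounding-box reference.

    Gap(k) = mean_ref[ln W_k(ref)] - ln W_k(data); the SE includes the
    sqrt(1 + 1/B) Monte-Carlo correction. Returns
    ``(gap, se, argmax_k, tibshirani_k)``: the k maximising the gap (the
    "higher the gap" reading) and the first k with
    Gap(k) >= Gap(k+1) - SE(k+1).
    """
    coords = np.asarray(coords, dtype=float)
    k_range = sorted(int(k) for k in k_range)
    rng = as_rng(seed)
    lo, hi = coords.min(axis=0), coords.max(axis=0)

    log_w_data = np.array(
        [np.log(max(kmeans(coords, k, seed=seed, n_init=n_init).wcss, 1e-300))
         for k in k_range]
    )
    log_w_ref = np.empty((n_refs, len(k_range)))
    for b in range(n_refs):
        ref = rng.uniform(lo, hi, size=coords.shape)
        ref_seed = int(rng.integers(2**31 - 1))
        for j, k in enumerate(k_range):
            w = kmeans(ref, k, seed=ref_seed, n_init=n_init).wcss
            log_w_ref[b, j] = np.log(max(w, 1e-300))

    gap = log_w_ref.mean(axis=0) - log_w_data
    se = log_w_ref.std(axis=0) * np.sqrt(1.0 + 1.0 / n_refs)
    argmax_k = k_range[int(np.argmax(gap))]
    tib_k = k_range[-1]
    for j in range(len(k_range) - 1):
        if gap[j] >= gap[j + 1] - se[j + 1]:
            tib_k = k_range[j]
            break
    return gap, se, argmax_k, tib_k


def k_selection_report(
    coords: np.ndarray,
    k_range,
    seed: int = 0,
    n_refs: int = 50,
    n_init: int = 10,
) -> KSelectionReport:
    """Elbow, silhouette and gap diagnostics over one range of k."""
    k_range = sorted(int(k) for k in k_range)
    wcss, knee_k = elbow_curve(coords, k_range, seed=seed, n_init=n_init)
    sils = []
    for k in k_range:
        if k < 2:
            sils.append(float("nan"))
            continue
        model = kmeans(coords, k, seed=seed, n_init=n_init)
        sils.append(silhouette(coords, model.labels)[1])
    gap, se, argmax_k, tib_k = gap_statistic(
        coords, k_range, n_refs=n_refs, seed=seed, n_init=n_init
    )
    finite = [s for s in sils if s == s]
    best_sil = k_range[sils.index(max(finite))] if finite else k_range[0]
    return KSelectionReport(
        k_range=k_range,
        wcss=wcss,
        mean_silhouette=sils,
        gap=list(gap),
        gap_se=list(se),
        recommended={
            "elbow": knee_k,
            "silhouette": best_sil,
            "gap": argmax_k,
            "gap_tibshirani": tib_k,
        },
    )
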