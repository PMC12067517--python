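"""Diffusion-based dimensionality reduction of avalanche patterns.

Implements a potential-of-heat-diffusion embedding built from first
principles: PCA preprocessing (default 5 components), cosine distances,
an adaptive-bandwidth alpha-decay kernel (default 5 nearest neighbours,
alpha = 1), Markov normalisation into a diffusion operator, diffusion-time
selection at the knee of the von Neumann entropy, log-potential distances,
and metric MDS into (default) 3 dimensions. A plain PCA path is exposed
through the same interface as the comparison method.

The kernel, normalisation, time selection and potential distances are the
method's core and are authored here; PCA and the SMACOF stress minimiser are
delegated to scikit-learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import smacof
from sklearn.metrics import pairwise_distances

from ._utils import check_finite, knee_point

__all__ = [
    "EmbeddingParams",
    "Embedding",
    "DegenerateBandwidthError",
    "pca_reduce",
    "cosine_distance_matrix",
    "alpha_decay_kernel",
    "markov_normalize",
    "von_neumann_entropy",
    "select_diffusion_time",
    "potential_distances",
    "mds_embed",
    "phate",
]


class DegenerateBandwidthError(ValueError):
    """A point's kNN bandwidth is zero (duplicate points in the input)."""


@dataclass
class EmbeddingParams:
    """Parameters of the diffusion embedding.

    Defaults are the analysis settings: 5 PCA components, cosine distance,
    5 nearest neighbours, alpha-decay 1, 3 output dimensions, diffusion time
    selected automatically at the von Neumann entropy knee.

    ``method='pca'`` short-circuits to plain PCA coordinates (the comparison
    method); ``potential='diffused_cosine'`` embeds distances between rows of
    the diffused operator instead of log-potential distances.
    """

    n_pca: int = 5
    distance: str = "cosine"
    knn: int = 5
    alpha: float = 1.0
    n_dims: int = 3
    t: int | str = "auto"  # positive int, or "auto" for the VNE knee
    t_max: int = 100
    mds_seed: int = 0
    mds_max_iter: int = 300
    method: str = "phate"  # "phate" or "pca"
    potential: str = "log"  # "log" or "diffused_cosine"

    def __post_init__(self):
        if self.knn < 1:
            raise ValueError("knn must be >= 1")
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")
        if self.n_dims < 1:
            raise ValueError("n_dims must be >= 1")
        if self.t != "auto" and (not isinstance(self.t, (int, np.integer)) or self.t < 1):
            raise ValueError("t must be a positive integer or 'auto'")
        if self.method not in ("phate", "pca"):
            raise ValueError("method must be 'phate' or 'pca'")
        if self.potential not in ("log", "diffused_cosine"):
            raise ValueError("potential must be 'log' or 'diffused_cosine'")


@dataclass
class Embedding:
    """Low-dimensional coordinates plus retained intermediates."""

    coords: np.ndarray
    params: EmbeddingParams
    explained_variance_ratio: np.ndarray
    t: int
    stress: float
    intermediates: dict = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]


def pca_reduce(x: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Column-centred PCA scores and explained-variance ratios.

    Components are ordered by decreasing variance. If the data rank is below
    ``n_components``, as many components as the rank are returned with a
    warning.
    """
    x = check_finite(np.asarray(x, dtype=float), "X")
    if x.shape[0] <= n_components:
        raise ValueError("need more observations than components")
    rank = np.linalg.matrix_rank(x - x.mean(axis=0))
    k = min(n_components, rank, x.shape[1])
    if k < n_components:
        warnings.warn(
            f"rank {rank} below requested {n_components} components; returning {k}",
            RuntimeWarning,
            stacklevel=2,
        )
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(x)
    return scores, model.explained_variance_ratio_


def cosine_distance_matrix(scores: np.ndarray) -> np.ndarray:
    """Pairwise cosine distances d(i,j) = 1 - cos(x_i, x_j), in [0, 2]."""
    scores = np.asarray(scores, dtype=float)
    norms = np.linalg.norm(scores, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero rows have no direction; cosine distance undefined")
    d = pairwise_distances(scores, metric="cosine")
    np.fill_diagonal(d, 0.0)
    # exact symmetry for downstream checks
    d = 0.5 * (d + d.T)
    return np.clip(d, 0.0, 2.0)


def _knn_bandwidth(d: np.ndarray, knn: int) -> np.ndarray:
    """Distance from each point to its knn-th nearest neighbour (self
    excluded; ties in distance leave the bandwidth value unchanged)."""
    n = d.shape[0]
    if knn > n - 1:
        raise ValueError(f"knn={knn} requires at least {knn + 1} points")
    work = d.copy()
    np.fill_diagonal(work, np.inf)  # exclude self
    return np.partition(work, knn - 1, axis=1)[:, knn - 1]


def alpha_decay_kernel(d: np.ndarray, knn: int = 5, alpha: float = 1.0) -> np.ndarray:
    """Adaptive-bandwidth alpha-decay affinity.

    K(i,j) = 1/2 [exp(-(d_ij / eps_k(i))^alpha) + exp(-(d_ij / eps_k(j))^alpha)]

    with eps_k(i) the distance from i to its ``knn``-th nearest neighbour
    (self excluded). Symmetric, entries in (0, 1], unit diagonal.
    """
    d = np.asarray(d, dtype=float)
    eps = _knn_bandwidth(d, knn)
    if np.any(eps == 0):
        raise DegenerateBandwidthError(
            "zero kNN bandwidth: duplicate points in the input "
            "(deduplicate patterns before embedding)"
        )
    a = np.exp(-((d / eps[:, None]) ** alpha))
    k = 0.5 * (a + a.T)
    np.fill_diagonal(k, 1.0)
    return k


def markov_normalize(kernel: np.ndarray) -> np.ndarray:
    """Row-normalise an affinity matrix into a row-stochastic diffusion
    operator P[i,j] = K[i,j] / sum_j K[i,j]."""
    kernel = np.asarray(kernel, dtype=float)
    if np.any(kernel < 0):
        raise ValueError("affinities must be nonnegative")
    rowsum = kernel.sum(axis=1, keepdims=True)
    if np.any(rowsum == 0):
        raise ValueError("zero-sum row cannot be Markov-normalised")
    return kernel / rowsum


def _stationary_distribution(
    p: np.ndarray, tol: float = 1e-13, max_iter: int = 2000
) -> np.ndarray:
    """Left stationary vector of a row-stochastic matrix by power iteration."""
    n = p.shape[0]
    pi = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = pi @ p
        total = nxt.sum()
        if total <= 0:
            break
        nxt /= total
        if np.abs(nxt - pi).max() < tol:
            return nxt
        pi = nxt
    return pi


def von_neumann_entropy(p: np.ndarray, t_max: int = 100) -> np.ndarray:
    """VNE(P^t) for t = 1..t_max from the spectrum of the symmetrised operator.

    P = D^-1 K is conjugate to the symmetric M = D^-1/2 K D^-1/2, so its
    eigenvalues are real; the entropy at time t is the Shannon entropy of the
    normalised |eigenvalue|^t spectrum.
    """
    p = np.asarray(p, dtype=float)
    # When P = D^-1 K with symmetric K, the left stationary vector pi is
    # proportional to the kernel row sums and M = diag(pi)^1/2 P diag(pi)^-1/2
    # is symmetric with the same (real) spectrum as P. Recover pi by power
    # iteration; residual asymmetry (non-kernel operators) is averaged out.
    pi = _stationary_distribution(p)
    s = np.sqrt(np.maximum(pi, 1e-300))
    m = (s[:, None] * p) / s[None, :]
    m = 0.5 * (m + m.T)
    lam = np.abs(np.linalg.eigvalsh(m))
    vne = np.empty(t_max)
    for i, t in enumerate(range(1, t_max + 1)):
        w = lam**t
        total = w.sum()
        if total <= 0:
            vne[i] = 0.0
            continue
        q = w / total
        q = q[q > 0]
        vne[i] = float(-(q * np.log(q)).sum())
    return vne


def select_diffusion_time(p: np.ndarray, t_max: int = 100) -> int:
    """Diffusion time at the knee of the von Neumann entropy curve.

    Falls back to t = 1 with a warning when the curve is flat (e.g. the
    identity operator).
    """
    vne = von_neumann_entropy(p, t_max=t_max)
    if np.allclose(vne, vne[0], atol=1e-12):
        warnings.warn(
            "von Neumann entropy is flat; falling back to t=1",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1
    return int(knee_point(np.arange(1, t_max + 1), vne)) + 1


def potential_distances(
    p: np.ndarray, t: int, prob_floor: float = 1e-12
) -> np.ndarray:
    """Potential distances between diffused rows.

    D_pot(i,j) = || log(P^t[i,:]) - log(P^t[j,:]) ||_2, probabilities floored
    at ``prob_floor`` so the log is defined everywhere. Symmetric, zero
    diagonal, and a metric (the Euclidean distance between log-row vectors).
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    pt = np.linalg.matrix_power(np.asarray(p, dtype=float), int(t))
    logs = np.log(np.maximum(pt, prob_floor))
    d = pairwise_distances(logs, metric="euclidean")
    np.fill_diagonal(d, 0.0)
    return 0.5 * (d + d.T)


def _classical_mds(d: np.ndarray, n_dims: int) -> np.ndarray:
    """Classical (Torgerson) MDS used as a deterministic SMACOF init."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d**2) @ j
    b = 0.5 * (b + b.T)
    lam, vec = np.linalg.eigh(b)
    order = np.argsort(lam)[::-1][:n_dims]
    lam_top = np.clip(lam[order], 0.0, None)
    coords = vec[:, order] * np.sqrt(lam_top)[None, :]
    # fix reflection ambiguity: largest-|value| entry of each axis positive
    for c in range(coords.shape[1]):
        col = coords[:, c]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            coords[:, c] = -col
    return coords


def mds_embed(
    dpot: np.ndarray,
    n_dims: int = 3,
    seed: int = 0,
    max_iter: int = 300,
    eps: float = 1e-6,
) -> tuple[np.ndarray, float]:
    """Metric MDS by SMACOF stress majorisation, initialised from classical
    MDS for determinism. Returns ``(coords, stress)``."""
    dpot = check_finite(np.asarray(dpot, dtype=float), "distance matrix")
    init = _classical_mds(dpot, n_dims)
    coords, stress = smacof(
        dpot,
        metric=True,
        n_components=n_dims,
        init=init,
        n_init=1,
        max_iter=max_iter,
        eps=eps,
        random_state=seed,
        normalized_stress=False,
    )
    return coords, float(stress)


def phate(
    x: np.ndarray,
    params: EmbeddingParams | None = None,
    keep_intermediates: bool = False,
) -> Embedding:
    """Full composition on a (U, N) matrix of unique avalanche patterns.

    PCA -> cosine distances -> alpha-decay kernel -> Markov normalisation ->
    diffusion-time selection -> potential distances -> metric MDS. With
    ``params.method='pca'`` the embedding is simply the first ``n_dims`` PCA
    scores (the comparison method), with explained variances still reported.
    """
    params = params or EmbeddingParams()
    x = np.asarray(x, dtype=float)
    n_pca = min(params.n_pca, x.shape[1])
    scores, evr = pca_reduce(x, n_pca)

    if params.method == "pca":
        coords = scores[:, : params.n_dims]
        return Embedding(
            coords=coords,
            params=params,
            explained_variance_ratio=evr,
            t=0,
            stress=float("nan"),
            intermediates={"pca_scores": scores} if keep_intermediates else {},
        )

    d = cosine_distance_matrix(scores)
    kernel = alpha_decay_kernel(d, knn=params.knn, alpha=params.alpha)
    p = markov_normalize(kernel)
    t = params.t if params.t != "auto" else select_diffusion_time(p, params.t_max)
    if params.potential == "log":
        dpot = potential_distances(p, t)
    else:
        # distances between diffused probability profiles (no log potential)
        pt = np.linalg.matrix_power(p, int(t))
        dpot = pairwise_distances(pt, metric="euclidean")
        np.fill_diagonal(dpot, 0.0)
        dpot = 0.5 * (dpot + dpot.T)
    coords, stress = mds_embed(
        dpot,
        n_dims=params.n_dims,
        seed=params.mds_seed,
        max_iter=params.mds_max_iter,
    )
    inter: dict = {}
    if keep_intermediates:
        inter = {
            "pca_scores": scores,
            "cosine_distances": d,
            "kernel": kernel,
            "diffusion_operator": p,
            "potential_distances": dpot,
        }
    return Embedding(
        coords=coords,
        params=params,
        explained_variance_ratio=evr,
        t=int(t),
        stress=stress,
        intermediates=inter,
    )
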