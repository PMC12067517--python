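"""Permutation null models and the Shannon-entropy statistic.

Three nulls probe three levels of structure:

1. *label shuffle* — cluster labels are permuted across avalanche patterns
   (cluster sizes preserved); tests whether the cluster topographies are more
   structured (lower entropy) than random groupings. Topographies are
   recomputed per permutation; the embedding is untouched.
2. *sequence shuffle* — the chronological order of state labels is permuted
   (within subject, or pooled); tests which transition probabilities sit
   above or below chance given the state occupancies.
3. *region shuffle* — region positions are permuted within every avalanche
   pattern (per-pattern active counts preserved) and the full embedding +
   clustering pipeline is re-run; tests whether the low-dimensional structure
   exceeds what region-exchangeable data produce (observed entropy above the
   null).

All empirical p-values use the add-one estimator
``p = (1 + #{null at least as extreme}) / (n_perm + 1)`` and are never 0.
Two-sided p-values double the smaller tail, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import as_rng
from .containers import PatternSequence
from .dynamics import (
    align_states,
    cluster_topographies,
    pooled_transition_matrix,
    propagate_labels,
    transition_matrix,
    TransitionMatrix,
)

__all__ = [
    "EntropyStat",
    "NullResult",
    "SignificanceMap",
    "SequenceNullResult",
    "cluster_entropy",
    "empirical_p",
    "two_sided_p",
    "null_label_shuffle",
    "null_sequence_shuffle",
    "null_region_shuffle",
    "transition_consistency",
    "method_entropy_comparison",
]


@dataclass(frozen=True)
class EntropyStat:
    """Shannon-form structure statistic of a concatenated cluster matrix.

    H = -sum_j x_j ln x_j over the length-M concatenation of the Nc
    topography rows (M = N x Nc), with 0 ln 0 = 0. The vector is *not*
    normalised to sum to one: H measures how far recruitment fractions sit
    from the deterministic values 0 and 1, in nats.
    """

    H: float
    M: int


@dataclass
class NullResult:
    observed: float
    null_values: np.ndarray
    p_low: float
    p_high: float
    n_perm: int
    seed: int


@dataclass
class SignificanceMap:
    """Trit matrix over (state, region): +1 recruited above chance,
    -1 excluded above chance, 0 neither; at significance level ``alpha``."""

    map: np.ndarray
    alpha: float
    p_high: np.ndarray = None
    p_low: np.ndarray = None

    def __post_init__(self):
        self.map = np.asarray(self.map, dtype=int)
        if not np.all(np.isin(self.map, (-1, 0, 1))):
            raise ValueError("significance map entries must be -1/0/+1")


@dataclass
class SequenceNullResult:
    observed: TransitionMatrix
    p_two_sided: np.ndarray
    p_high: np.ndarray
    p_low: np.ndarray
    mask: np.ndarray  # trit matrix at alpha
    alpha: float
    n_perm: int
    seed: int


def cluster_entropy(fractions: np.ndarray) -> EntropyStat:
    """Entropy of the concatenated topography matrix (nats).

    Entries must be recruitment fractions in [0, 1]; concatenation order is
    immaterial since the sum is order-invariant.
    """
    x = np.asarray(fractions, dtype=float).ravel()
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("recruitment fractions must lie in [0, 1]")
    pos = x[x > 0]
    h = float(-(pos * np.log(pos)).sum())
    return EntropyStat(H=h, M=x.size)


def empirical_p(observed: float, null_values: np.ndarray, tail: str) -> float:
    """Add-one empirical tail probability; never 0."""
    null_values = np.asarray(null_values, dtype=float)
    n = null_values.size
    if tail == "low":
        extreme = int((null_values <= observed).sum())
    elif tail == "high":
        extreme = int((null_values >= observed).sum())
    else:
        raise ValueError("tail must be 'low' or 'high'")
    return (1 + extreme) / (n + 1)


def two_sided_p(observed: float, null_values: np.ndarray) -> float:
    """Two-sided p by doubling the smaller add-one tail, capped at 1."""
    lo = empirical_p(observed, null_values, "low")
    hi = empirical_p(observed, null_values, "high")
    return min(1.0, 2.0 * min(lo, hi))


def _trit_map(
    obs: np.ndarray, null: np.ndarray, alpha: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cellwise trit map from an (n_perm, ...) null stack.

    +1 where the doubled-tail p is <= alpha and the observed value sits in
    the upper tail, -1 for the lower tail, else 0.
    """
    n = null.shape[0]
    p_high = (1 + (null >= obs[None]).sum(axis=0)) / (n + 1)
    p_low = (1 + (null <= obs[None]).sum(axis=0)) / (n + 1)
    p_two = np.minimum(1.0, 2.0 * np.minimum(p_high, p_low))
    trit = np.zeros(obs.shape, dtype=int)
    trit[(p_two <= alpha) & (p_high < p_low)] = 1
    trit[(p_two <= alpha) & (p_low < p_high)] = -1
    return trit, p_high, p_low


def null_label_shuffle(
    patterns: PatternSequence | np.ndarray,
    labels: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[NullResult, SignificanceMap]:
    """Null model 1: permute cluster labels across patterns.

    Each permutation reassigns the observed labels to the patterns uniformly
    at random (preserving cluster sizes), recomputes the topographies and
    their entropy. Structured clusterings have entropy *below* the null
    (``p_low``). The per-(state, region) recruitment fractions are compared
    two-sided against their null distributions into a trit map at ``alpha``.
    """
    import warnings

    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives unstable p-values", RuntimeWarning, stacklevel=2
        )
    mat = patterns.patterns if isinstance(patterns, PatternSequence) else np.asarray(patterns)
    labels = np.asarray(labels, dtype=int)
    rng = as_rng(seed)
    k = int(labels.max()) + 1
    obs_topo = cluster_topographies(mat, labels, k=k)
    obs_h = cluster_entropy(obs_topo.fractions).H

    mat_i = mat.astype(np.int64)
    null_h = np.empty(n_perm)
    null_frac = np.empty((n_perm, k, mat.shape[1]))
    sizes = obs_topo.cluster_sizes[:, None]
    for b in range(n_perm):
        perm = rng.permutation(labels)
        onehot = np.zeros((mat.shape[0], k), dtype=np.int64)
        onehot[np.arange(mat.shape[0]), perm] = 1
        counts = onehot.T @ mat_i
        frac = counts / sizes
        null_frac[b] = frac
        null_h[b] = cluster_entropy(frac).H

    result = NullResult(
        observed=obs_h,
        null_values=null_h,
        p_low=empirical_p(obs_h, null_h, "low"),
        p_high=empirical_p(obs_h, null_h, "high"),
        n_perm=n_perm,
        seed=int(seed) if np.isscalar(seed) else -1,
    )
    trit, p_high, p_low = _trit_map(obs_topo.fractions, null_frac, alpha)
    return result, SignificanceMap(map=trit, alpha=alpha, p_high=p_high, p_low=p_low)


def null_sequence_shuffle(
    sequences: dict[str, np.ndarray] | list[np.ndarray] | np.ndarray,
    k: int,
    n_perm: int = 10000,
    seed: int = 0,
    pooled: bool = False,
    alpha: float = 0.05,
    one_sided: str | None = None,
) -> SequenceNullResult:
    """Null model 2: permute the chronological order of state labels.

    Label counts (state occupancies) are preserved exactly. In per-subject
    mode each subject's sequence is shuffled independently and the
    within-subject transition counts pooled (boundary-excluded); in pooled
    mode the concatenated sequence is shuffled as one. Per-cell transition
    probabilities are compared against their null distributions; the default
    is two-sided (doubled tail), ``one_sided='high'``/``'low'`` restricts the
    test direction.
    """
    if isinstance(sequences, np.ndarray):
        sequences = [sequences]
    if isinstance(sequences, dict):
        seqs = [np.asarray(s, dtype=int) for s in sequences.values()]
    else:
        seqs = [np.asarray(s, dtype=int) for s in sequences]
    if any(s.size < 2 for s in seqs) and not pooled:
        seqs = [s for s in seqs if s.size >= 2]
    if not seqs:
        raise ValueError("need at least one sequence of length >= 2")
    rng = as_rng(seed)

    if pooled:
        cat = np.concatenate(seqs)
        observed = transition_matrix(cat, k, subject_id="pooled")
    else:
        observed = pooled_transition_matrix(seqs, k, boundary_policy="exclude")

    null_probs = np.empty((n_perm, k, k))
    for b in range(n_perm):
        if pooled:
            null_probs[b] = transition_matrix(rng.permutation(cat), k).probs
        else:
            shuffled = [rng.permutation(s) for s in seqs]
            null_probs[b] = pooled_transition_matrix(
                shuffled, k, boundary_policy="exclude"
            ).probs

    obs = observed.probs
    n = n_perm
    p_high = (1 + (null_probs >= obs[None]).sum(axis=0)) / (n + 1)
    p_low = (1 + (null_probs <= obs[None]).sum(axis=0)) / (n + 1)
    if one_sided == "high":
        p = p_high
        trit = np.where(p <= alpha, 1, 0)
    elif one_sided == "low":
        p = p_low
        trit = np.where(p <= alpha, -1, 0)
    elif one_sided is None:
        p = np.minimum(1.0, 2.0 * np.minimum(p_high, p_low))
        trit = np.zeros((k, k), dtype=int)
        trit[(p <= alpha) & (p_high < p_low)] = 1
        trit[(p <= alpha) & (p_low < p_high)] = -1
    else:
        raise ValueError("one_sided must be None, 'high' or 'low'")
    return SequenceNullResult(
        observed=observed,
        p_two_sided=p if one_sided is None else np.minimum(1.0, 2 * np.minimum(p_high, p_low)),
        p_high=p_high,
        p_low=p_low,
        mask=trit,
        alpha=alpha,
        n_perm=n_perm,
        seed=int(seed) if np.isscalar(seed) else -1,
    )


def _labels_via_pipeline(
    mat: np.ndarray,
    k: int,
    embedding_params,
    kmeans_seed: int,
    kmeans_n_init: int,
) -> np.ndarray:
    """Unique -> embed -> k-means -> propagate, returning one label per
    pattern occurrence.

    When there are no more unique patterns than requested clusters the
    embedding is redundant (k-means with k >= U separates every unique
    pattern); each unique pattern then becomes its own cluster. This also
    covers degenerate shuffles (e.g. all-ones patterns) gracefully.
    """
    from .avalanche import _unique_rows_first_occurrence
    from .clustering import kmeans as _kmeans
    from .embedding import phate

    uniq, index = _unique_rows_first_occurrence(mat)
    u = uniq.shape[0]
    if u <= k or u <= embedding_params.n_pca + 1:
        return propagate_labels(np.arange(u), index)
    emb = phate(uniq, embedding_params)
    model = _kmeans(emb.coords, k, seed=kmeans_seed, n_init=kmeans_n_init)
    return propagate_labels(model.labels, index)


def null_region_shuffle(
    patterns: PatternSequence | np.ndarray,
    embedding_params=None,
    k: int = 7,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.2,
    kmeans_seed: int = 0,
    kmeans_n_init: int = 10,
) -> tuple[NullResult, SignificanceMap]:
    """Null model 3: permute region positions within every pattern and re-run
    the full embedding + clustering pipeline per permutation.

    Each permutation independently permutes the region axis of every pattern
    (preserving each pattern's active count while destroying cross-pattern
    region identity), re-runs PCA -> kernel -> diffusion -> MDS -> k-means,
    recomputes topographies over all occurrences and their entropy. A
    structure-preserving embedding keeps the observed entropy *above* this
    null (``p_high``). Per-(state, region) fractions feed a trit map at
    ``alpha`` (default 0.2), with each permutation's clusters aligned to the
    observed clusters by correlation before the cellwise comparison.

    The default ``n_perm`` is 999: this null re-runs the embedding for every
    permutation, so the permutation count trades against runtime; pass a
    larger value for final analyses.
    """
    from .embedding import EmbeddingParams

    embedding_params = embedding_params or EmbeddingParams()
    mat = patterns.patterns if isinstance(patterns, PatternSequence) else np.asarray(patterns)
    mat = mat.astype(np.uint8)
    rng = as_rng(seed)
    n_pat, n_reg = mat.shape

    obs_labels = _labels_via_pipeline(
        mat, k, embedding_params, kmeans_seed, kmeans_n_init
    )
    k_obs = int(obs_labels.max()) + 1
    obs_topo = cluster_topographies(mat, obs_labels, k=k_obs)
    obs_h = cluster_entropy(obs_topo.fractions).H

    null_h = np.empty(n_perm)
    null_frac = np.full((n_perm, k_obs, n_reg), np.nan)
    for b in range(n_perm):
        shuffled = np.empty_like(mat)
        for i in range(n_pat):
            shuffled[i] = mat[i, rng.permutation(n_reg)]
        lab = _labels_via_pipeline(
            shuffled, k, embedding_params, kmeans_seed, kmeans_n_init
        )
        k_b = int(lab.max()) + 1
        topo = cluster_topographies(shuffled, lab, k=k_b)
        null_h[b] = cluster_entropy(topo.fractions).H
        if k_b == k_obs:
            perm = align_states(topo, obs_topo)
            aligned = np.empty_like(topo.fractions)
            aligned[perm] = topo.fractions
            null_frac[b] = aligned

    result = NullResult(
        observed=obs_h,
        null_values=null_h,
        p_low=empirical_p(obs_h, null_h, "low"),
        p_high=empirical_p(obs_h, null_h, "high"),
        n_perm=n_perm,
        seed=int(seed) if np.isscalar(seed) else -1,
    )
    valid = ~np.isnan(null_frac).any(axis=(1, 2))
    if valid.any():
        trit, p_high, p_low = _trit_map(
            obs_topo.fractions, null_frac[valid], alpha
        )
    else:
        trit = np.zeros_like(obs_topo.fractions, dtype=int)
        p_high = p_low = np.ones_like(obs_topo.fractions)
    return result, SignificanceMap(map=trit, alpha=alpha, p_high=p_high, p_low=p_low)


def transition_consistency(masks: list[np.ndarray]) -> dict[str, np.ndarray]:
    """Tally, per transition cell, how many subjects flag it in the same
    direction (above chance / below chance)."""
    stack = np.stack([np.asarray(m, dtype=int) for m in masks])
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise ValueError("masks must be square matrices of equal K")
    return {
        "above": (stack == 1).sum(axis=0),
        "below": (stack == -1).sum(axis=0),
        "n_subjects": stack.shape[0],
    }


def method_entropy_comparison(
    labelings: list[tuple[str, np.ndarray]],
    patterns: PatternSequence | np.ndarray,
) -> pd.DataFrame:
    """Entropy of the cluster matrix under several labelings of the same
    patterns (e.g. different reduction methods), as a comparison table.

    Lower entropy indicates more deterministic (structured) topographies;
    intermediate values balance structure against information richness.
    """
    mat = patterns.patterns if isinstance(patterns, PatternSequence) else np.asarray(patterns)
    rows = []
    for name, labels in labelings:
        labels = np.asarray(labels, dtype=int)
        if labels.shape[0] != mat.shape[0]:
            raise ValueError(f"labeling '{name}' does not cover all patterns")
        k = int(labels.max()) + 1
        topo = cluster_topographies(mat, labels, k=k)
        h = cluster_entropy(topo.fractions)
        rows.append({"method": name, "k": k, "entropy_nats": h.H, "M": h.M})
    return pd.DataFrame(rows)
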