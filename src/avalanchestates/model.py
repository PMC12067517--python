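"""Model/Results interface over the full pipeline.

:class:`AvalancheStateModel` is built from data (a list of
:class:`~avalanchestates.containers.SignalSet`, or directly from a
:class:`~avalanchestates.containers.PatternSequence`); ``fit()`` executes
detection -> unique patterns -> diffusion embedding -> k-means -> label
propagation -> topographies -> transition matrices and returns an
:class:`AvalancheStateResults` carrying the estimates, diagnostics and
``summary()`` table. Permutation tests, model selection and plotting hang
off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .avalanche import (
    avalanche_summary,
    binarize,
    detect_avalanches,
    extract_patterns,
    unique_patterns,
    zscore,
)
from .clustering import ClusterModel, k_selection_report, kmeans
from .containers import PatternSequence, SignalSet
from .dynamics import (
    TopographyMatrix,
    TransitionMatrix,
    cluster_topographies,
    label_sequences_by_subject,
    pooled_transition_matrix,
    propagate_labels,
    transition_matrix,
    transition_variability,
)
from .embedding import Embedding, EmbeddingParams, phate
from .nullmodels import (
    cluster_entropy,
    null_label_shuffle,
    null_region_shuffle,
    null_sequence_shuffle,
)

__all__ = ["AvalancheStateModel", "AvalancheStateResults"]


class AvalancheStateModel:
    """Brain-state model over neuronal avalanche patterns.

    Parameters
    ----------
    signals : list of SignalSet, optional
        One region x time signal set per subject.
    patterns : PatternSequence, optional
        Pre-extracted avalanche patterns (alternative to ``signals``).
    threshold : float
        z-threshold for binarisation (SD units), default 3.
    binarize_mode : {"absolute", "positive"}
    embedding : EmbeddingParams
        Diffusion-embedding settings (default: 5 PCA components, cosine,
        5-NN, alpha 1, 3 dims, automatic diffusion time).
    k : int
        Number of states for k-means, default 7.
    boundary_policy : {"exclude", "include"}
        Cross-subject boundary handling when pooling transitions.

    Examples
    --------
    >>> model = AvalancheStateModel(signals, k=7)
    >>> res = model.fit(seed=11)
    >>> print(res.summary())
    """

    def __init__(
        self,
        signals: list[SignalSet] | None = None,
        patterns: PatternSequence | None = None,
        threshold: float = 3.0,
        binarize_mode: str = "absolute",
        embedding: EmbeddingParams | None = None,
        k: int = 7,
        kmeans_n_init: int = 50,
        boundary_policy: str = "exclude",
    ):
        if (signals is None) == (patterns is None):
            raise ValueError("provide exactly one of signals or patterns")
        self.signals = signals
        self._patterns = patterns
        self.threshold = threshold
        self.binarize_mode = binarize_mode
        self.embedding_params = embedding or EmbeddingParams()
        self.k = k
        self.kmeans_n_init = kmeans_n_init
        self.boundary_policy = boundary_policy

    @classmethod
    def from_patterns(cls, patterns: PatternSequence, **kwargs) -> "AvalancheStateModel":
        return cls(patterns=patterns, **kwargs)

    def extract_patterns(self) -> tuple[PatternSequence, list]:
        """Detection stage only: avalanche patterns plus per-subject
        summaries (count/size/duration/sparsity)."""
        if self._patterns is not None:
            return self._patterns, []
        per_subject = []
        summaries = []
        for sig in self.signals:
            raster = binarize(zscore(sig), self.threshold, self.binarize_mode)
            intervals = detect_avalanches(raster)
            summaries.append(avalanche_summary(raster, intervals))
            if intervals:
                per_subject.append(extract_patterns(raster, intervals))
        if not per_subject:
            raise ValueError("no avalanches detected in any subject")
        return PatternSequence.concatenate(per_subject), summaries

    def fit(self, seed: int = 0) -> "AvalancheStateResults":
        """Run the full pipeline; deterministic given ``seed``."""
        seq, summaries = self.extract_patterns()
        uniq, index = unique_patterns(seq)
        emb_params = self.embedding_params
        if emb_params.mds_seed != seed:
            from dataclasses import replace

            emb_params = replace(emb_params, mds_seed=seed)
        embedding = phate(uniq, emb_params)
        k = min(self.k, uniq.shape[0])
        cluster = kmeans(
            embedding.coords, k, seed=seed, n_init=self.kmeans_n_init
        )
        labels = propagate_labels(cluster.labels, index)
        topography = cluster_topographies(seq, labels, k=k)
        sequences = label_sequences_by_subject(seq, labels)
        per_subject_tm = {
            s: transition_matrix(v, k, subject_id=s) for s, v in sequences.items()
        }
        pooled_tm = pooled_transition_matrix(
            sequences, k, boundary_policy=self.boundary_policy
        )
        return AvalancheStateResults(
            model=self,
            patterns=seq,
            unique_patterns=uniq,
            occurrence_index=index,
            embedding=embedding,
            cluster=cluster,
            labels=labels,
            topography=topography,
            label_sequences=sequences,
            per_subject_transitions=per_subject_tm,
            pooled_transition=pooled_tm,
            avalanche_summaries=summaries,
            seed=seed,
        )


@dataclass
class AvalancheStateResults:
    """Fitted state model: labels, topographies, transitions, diagnostics."""

    model: AvalancheStateModel
    patterns: PatternSequence
    unique_patterns: np.ndarray
    occurrence_index: np.ndarray
    embedding: Embedding
    cluster: ClusterModel
    labels: np.ndarray
    topography: TopographyMatrix
    label_sequences: dict[str, np.ndarray]
    per_subject_transitions: dict[str, TransitionMatrix]
    pooled_transition: TransitionMatrix
    avalanche_summaries: list = field(default_factory=list)
    seed: int = 0

    # -- scalar diagnostics -------------------------------------------------
    @property
    def k(self) -> int:
        return self.cluster.k

    @property
    def n_avalanches(self) -> int:
        return self.patterns.n_patterns

    @property
    def n_unique(self) -> int:
        return self.unique_patterns.shape[0]

    @property
    def entropy(self) -> float:
        """Entropy (nats) of the concatenated topography matrix."""
        return cluster_entropy(self.topography.fractions).H

    @property
    def ctm_diagonal_mean(self) -> float:
        """Mean self-transition probability of the pooled transition matrix."""
        return float(np.diag(self.pooled_transition.probs).mean())

    def transition_variability(self):
        return transition_variability(list(self.per_subject_transitions.values()))

    # -- permutation tests --------------------------------------------------
    def label_shuffle_test(self, n_perm: int = 10000, seed: int = 0, alpha: float = 0.05):
        """Null model 1: are the topographies more structured than random
        label assignments? (observed entropy in the lower tail)"""
        return null_label_shuffle(
            self.patterns, self.labels, n_perm=n_perm, seed=seed, alpha=alpha
        )

    def sequence_shuffle_test(
        self,
        n_perm: int = 10000,
        seed: int = 0,
        alpha: float = 0.05,
        pooled: bool = False,
        one_sided: str | None = None,
    ):
        """Null model 2: which transitions occur above/below chance?"""
        return null_sequence_shuffle(
            self.label_sequences,
            self.k,
            n_perm=n_perm,
            seed=seed,
            pooled=pooled,
            alpha=alpha,
            one_sided=one_sided,
        )

    def region_shuffle_test(
        self,
        n_perm: int = 999,
        seed: int = 0,
        alpha: float = 0.2,
        kmeans_n_init: int = 10,
    ):
        """Null model 3: does the embedding retain structure that
        region-exchangeable patterns lack? (observed entropy in the upper
        tail)"""
        return null_region_shuffle(
            self.patterns,
            embedding_params=self.embedding.params,
            k=self.k,
            n_perm=n_perm,
            seed=seed,
            alpha=alpha,
            kmeans_seed=self.seed,
            kmeans_n_init=kmeans_n_init,
        )

    # -- model selection ----------------------------------------------------
    def k_selection(self, k_range=range(2, 13), seed: int = 0, n_refs: int = 50,
                    n_init: int = 10):
        """Elbow / silhouette / gap diagnostics on the fitted embedding."""
        return k_selection_report(
            self.embedding.coords, k_range, seed=seed, n_refs=n_refs, n_init=n_init
        )

    # -- presentation --------------------------------------------------------
    def summary(self) -> str:
        lines = []
        emb = self.embedding
        subjects = self.patterns.subjects()
        evr = np.asarray(emb.explained_variance_ratio)
        w = 66
        lines.append("Avalanche State Model Results".center(w))
        lines.append("=" * w)
        rows = [
            ("No. subjects:", f"{len(subjects)}"),
            ("No. avalanches:", f"{self.n_avalanches}"),
            ("No. unique patterns:", f"{self.n_unique}"),
            ("No. regions:", f"{self.patterns.n_regions}"),
            ("Embedding:", emb.params.method),
            ("  PCA components:", f"{emb.params.n_pca}"),
            ("  cum. explained var.:", f"{evr.sum():.3f}"),
            ("  kNN / alpha:", f"{emb.params.knn} / {emb.params.alpha:g}"),
            ("  diffusion time t:", f"{emb.t}"),
            ("  MDS stress:", f"{emb.stress:.4g}"),
            ("States (k):", f"{self.k}"),
            ("  WCSS:", f"{self.cluster.wcss:.4g}"),
            ("  entropy (nats):", f"{self.entropy:.4f}"),
            ("CTM diagonal mean:", f"{self.ctm_diagonal_mean:.4f}"),
            ("Boundary policy:", self.pooled_transition.boundary_policy),
            ("Seed:", f"{self.seed}"),
        ]
        for name, value in rows:
            lines.append(f"{name:<28}{value:>38}")
        lines.append("-" * w)
        lines.append("State occupancy (fraction of avalanches):")
        occ = np.bincount(self.labels, minlength=self.k) / self.n_avalanches
        lines.append("  " + "  ".join(f"s{i}:{o:.3f}" for i, o in enumerate(occ)))
        lines.append("=" * w)
        return "\n".join(lines)

    # -- plotting ------------------------------------------------------------
    def plot_embedding(self, ax=None, dims=(0, 1)):
        """Scatter of the embedded patterns coloured by state label."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        coords = self.embedding.coords
        ulabels = self.cluster.labels
        sc = ax.scatter(coords[:, dims[0]], coords[:, dims[1]], c=ulabels,
                        s=8, cmap="tab10")
        ax.set_xlabel(f"axis {dims[0] + 1}")
        ax.set_ylabel(f"axis {dims[1] + 1}")
        ax.set_title("Diffusion embedding of avalanche patterns")
        return ax

    def plot_transition_matrix(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.pooled_transition.probs, cmap="viridis", vmin=0)
        ax.figure.colorbar(im, ax=ax, label="P(next | current)")
        ax.set_xlabel("to state")
        ax.set_ylabel("from state")
        ax.set_title("Pooled state transition matrix")
        return ax
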