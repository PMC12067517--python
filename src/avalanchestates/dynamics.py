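"""State topographies and transition dynamics.

Once every avalanche pattern carries a state label, states are characterised
by their *topography* (per-region recruitment frequency among the patterns of
that state) and their dynamics by per-subject and pooled K x K transition
matrices, intersubject variability of the transitions, and cross-run /
cross-cohort matching of topographies by correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .containers import PatternSequence

__all__ = [
    "TopographyMatrix",
    "TransitionMatrix",
    "TransitionVariability",
    "cluster_topographies",
    "propagate_labels",
    "label_sequences_by_subject",
    "transition_matrix",
    "pooled_transition_matrix",
    "transition_variability",
    "match_clusterings",
    "align_states",
    "threshold_sensitivity_scan",
]


@dataclass
class TopographyMatrix:
    """Per-state recruitment of each region.

    ``fractions[s, r]`` is the fraction of state-s patterns recruiting region
    r (counts / cluster size, in [0, 1]); ``counts`` the raw tallies.
    """

    fractions: np.ndarray
    counts: np.ndarray
    cluster_sizes: np.ndarray
    region_labels: list[str] | None = None

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        self.cluster_sizes = np.asarray(self.cluster_sizes, dtype=int)
        if self.fractions.shape != self.counts.shape:
            raise ValueError("fractions and counts must have the same shape")
        if np.any(self.fractions < 0) or np.any(self.fractions > 1):
            raise ValueError("fractions must lie in [0, 1]")

    @property
    def n_states(self) -> int:
        return self.fractions.shape[0]

    @property
    def n_regions(self) -> int:
        return self.fractions.shape[1]


@dataclass
class TransitionMatrix:
    """Row-stochastic K x K state-transition probabilities with raw counts.

    Rows whose state never occurs as a transition source have zero counts;
    they are left all-zero and flagged in ``zero_rows``.
    """

    probs: np.ndarray
    counts: np.ndarray
    subject_id: str = "pooled"
    boundary_policy: str = "exclude"
    zero_rows: np.ndarray = field(default=None)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.zero_rows is None:
            self.zero_rows = self.counts.sum(axis=1) == 0
        row_tot = self.counts.sum(axis=1)
        live = row_tot > 0
        if live.any() and not np.allclose(
            self.probs[live].sum(axis=1), 1.0, atol=1e-12
        ):
            raise ValueError("rows with counts must sum to 1")
        if (~live).any() and not np.allclose(self.probs[~live], 0.0):
            raise ValueError("zero-count rows must be all-zero")

    @property
    def k(self) -> int:
        return self.probs.shape[0]


@dataclass
class TransitionVariability:
    """Cellwise mean / SD / coefficient of variation across subjects.

    CV is NaN where the cellwise mean is 0; ``n_subjects_per_cell`` counts
    subjects whose source row was non-empty for that cell.
    """

    mean: np.ndarray
    sd: np.ndarray
    cv: np.ndarray
    n_subjects_per_cell: np.ndarray


def cluster_topographies(
    patterns: PatternSequence | np.ndarray,
    labels: np.ndarray,
    k: int | None = None,
) -> TopographyMatrix:
    """Recruitment counts and fractions per (state, region).

    ``labels`` assigns a state to every pattern occurrence (propagated from
    unique-pattern labels). Raises on an empty cluster.
    """
    if isinstance(patterns, PatternSequence):
        mat = patterns.patterns
        region_labels = patterns.region_labels
    else:
        mat = np.asarray(patterns)
        region_labels = None
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != mat.shape[0]:
        raise ValueError("one label per pattern required")
    k = int(k) if k is not None else int(labels.max()) + 1
    sizes = np.bincount(labels, minlength=k)
    if np.any(sizes == 0):
        empty = np.flatnonzero(sizes == 0).tolist()
        raise ValueError(f"empty cluster(s): {empty}")
    onehot = np.zeros((mat.shape[0], k), dtype=np.int64)
    onehot[np.arange(mat.shape[0]), labels] = 1
    counts = onehot.T @ mat.astype(np.int64)
    fractions = counts / sizes[:, None]
    return TopographyMatrix(
        fractions=fractions,
        counts=counts,
        cluster_sizes=sizes,
        region_labels=region_labels,
    )


def propagate_labels(
    unique_labels: np.ndarray, occurrence_index: np.ndarray
) -> np.ndarray:
    """Map unique-pattern labels back to every original occurrence."""
    unique_labels = np.asarray(unique_labels, dtype=int)
    occurrence_index = np.asarray(occurrence_index, dtype=int)
    if occurrence_index.min() < 0 or occurrence_index.max() >= unique_labels.shape[0]:
        raise IndexError("occurrence index out of range")
    return unique_labels[occurrence_index]


def label_sequences_by_subject(
    seq: PatternSequence, labels: np.ndarray
) -> dict[str, np.ndarray]:
    """Chronological state-label sequence per subject."""
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != seq.n_patterns:
        raise ValueError("one label per avalanche required")
    return {s: labels[rows] for s, rows in seq.split_by_subject().items()}


def transition_matrix(
    label_sequence: np.ndarray, k: int, subject_id: str = "subject"
) -> TransitionMatrix:
    """Empirical transition counts and row-normalised probabilities.

    A sequence shorter than 2 yields all-zero counts with every row flagged.
    """
    seq = np.asarray(label_sequence, dtype=int)
    counts = np.zeros((k, k), dtype=np.int64)
    if seq.size >= 2:
        np.add.at(counts, (seq[:-1], seq[1:]), 1)
    probs = _normalise_counts(counts)
    return TransitionMatrix(
        probs=probs, counts=counts, subject_id=subject_id,
        boundary_policy="exclude",
    )


def _normalise_counts(counts: np.ndarray) -> np.ndarray:
    row_tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(row_tot > 0, counts / np.maximum(row_tot, 1), 0.0)
    return probs


def pooled_transition_matrix(
    sequences: dict[str, np.ndarray] | list[np.ndarray],
    k: int,
    boundary_policy: str = "exclude",
) -> TransitionMatrix:
    """Cohort-level transition matrix.

    ``exclude`` (default) sums within-subject transition counts only, the
    statistically correct pooling. ``include`` concatenates the sequences
    first, adding one spurious cross-subject boundary pair per junction —
    offered for fidelity with pooled-concatenation analyses that accept those
    few false transitions.
    """
    if isinstance(sequences, dict):
        seqs = list(sequences.values())
    else:
        seqs = list(sequences)
    if not seqs:
        raise ValueError("need at least one subject")
    counts = np.zeros((k, k), dtype=np.int64)
    if boundary_policy == "exclude":
        for s in seqs:
            s = np.asarray(s, dtype=int)
            if s.size >= 2:
                np.add.at(counts, (s[:-1], s[1:]), 1)
    elif boundary_policy == "include":
        cat = np.concatenate([np.asarray(s, dtype=int) for s in seqs])
        if cat.size >= 2:
            np.add.at(counts, (cat[:-1], cat[1:]), 1)
    else:
        raise ValueError("boundary_policy must be 'exclude' or 'include'")
    return TransitionMatrix(
        probs=_normalise_counts(counts),
        counts=counts,
        subject_id="pooled",
        boundary_policy=boundary_policy,
    )


def transition_variability(
    matrices: list[TransitionMatrix],
) -> TransitionVariability:
    """Cellwise mean, population SD and CV of transition probabilities across
    subjects; subjects whose source row is empty are excluded cellwise."""
    ks = {m.k for m in matrices}
    if len(ks) != 1:
        raise ValueError("all matrices must share the same K")
    k = ks.pop()
    stack = np.stack([m.probs for m in matrices])  # (S, K, K)
    valid = np.stack(
        [~m.zero_rows[:, None] & np.ones((k, k), bool) for m in matrices]
    )
    n_valid = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(
            n_valid > 0, (stack * valid).sum(axis=0) / np.maximum(n_valid, 1), np.nan
        )
        sq = ((stack - np.where(np.isnan(mean), 0, mean)) ** 2) * valid
        sd = np.where(n_valid > 0, np.sqrt(sq.sum(axis=0) / np.maximum(n_valid, 1)), np.nan)
        cv = np.where(mean > 0, sd / mean, np.nan)
    return TransitionVariability(mean=mean, sd=sd, cv=cv, n_subjects_per_cell=n_valid)


def _row_correlations(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of a and every row of b.

    Constant rows have undefined correlation; they are flagged with a warning
    and scored 0 against every counterpart.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    an = np.linalg.norm(ac, axis=1)
    bn = np.linalg.norm(bc, axis=1)
    if np.any(an == 0) or np.any(bn == 0):
        warnings.warn(
            "constant topography row(s): correlation undefined, scored 0",
            RuntimeWarning,
            stacklevel=2,
        )
    denom = np.outer(np.where(an == 0, np.inf, an), np.where(bn == 0, np.inf, bn))
    return (ac @ bc.T) / denom


def match_clusterings(
    topo_a: TopographyMatrix | np.ndarray,
    topo_b: TopographyMatrix | np.ndarray,
) -> tuple[np.ndarray, list[tuple[int, int]], float]:
    """Correlation-based matching of two sets of state topographies.

    Returns ``(correlation matrix, per-row best match, average max
    correlation)``. The matching is greedy per row of A (each A state picks
    its best-correlated B state, many-to-one allowed); the summary statistic
    is the mean over A states of their maximum correlation (directional,
    A -> B).
    """
    a = topo_a.fractions if isinstance(topo_a, TopographyMatrix) else np.asarray(topo_a)
    b = topo_b.fractions if isinstance(topo_b, TopographyMatrix) else np.asarray(topo_b)
    if a.shape[1] != b.shape[1]:
        raise ValueError("topographies must share the region dimension")
    corr = _row_correlations(a, b)
    best = corr.argmax(axis=1)
    matching = [(i, int(j)) for i, j in enumerate(best)]
    avg_max = float(corr.max(axis=1).mean())
    return corr, matching, avg_max


def align_states(
    topo_a: TopographyMatrix | np.ndarray,
    topo_b: TopographyMatrix | np.ndarray,
) -> np.ndarray:
    """One-to-one assignment of A states to B states (Hungarian algorithm on
    the correlation matrix). Returns ``perm`` with ``perm[i]`` the B state
    assigned to A state i. Requires equal state counts."""
    corr, _, _ = match_clusterings(topo_a, topo_b)
    if corr.shape[0] != corr.shape[1]:
        raise ValueError("align_states requires equal numbers of states")
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(corr.shape[0], dtype=int)
    perm[rows] = cols
    return perm


def threshold_sensitivity_scan(
    signal_sets,
    thresholds,
    *,
    reference_threshold: float = 3.0,
    mode: str = "absolute",
    embedding_params=None,
    k: int = 7,
    kmeans_seed: int = 0,
    kmeans_n_init: int = 10,
) -> dict[float, dict]:
    """Re-run the full pipeline at several z-thresholds.

    For each threshold: detect avalanches, embed unique patterns, cluster,
    compute topographies, and report the cluster-matrix entropy plus the
    average max correlation of the topographies against the
    reference-threshold run. Thresholds that yield no avalanches are recorded
    as missing (``None``) rather than failing the scan.
    """
    from .avalanche import signals_to_patterns, unique_patterns
    from .containers import PatternSequence
    from .embedding import EmbeddingParams, phate
    from .nullmodels import cluster_entropy

    def run_one(threshold: float):
        per_subject = []
        for sig in signal_sets:
            ps = signals_to_patterns(sig, threshold=threshold, mode=mode)
            if ps.n_patterns:
                per_subject.append(ps)
        if not per_subject:
            return None
        seq = PatternSequence.concatenate(per_subject)
        uniq, index = unique_patterns(seq)
        params = embedding_params or EmbeddingParams()
        emb = phate(uniq, params)
        from .clustering import kmeans as _kmeans

        model = _kmeans(
            emb.coords, min(k, uniq.shape[0]), seed=kmeans_seed, n_init=kmeans_n_init
        )
        labels = propagate_labels(model.labels, index)
        topo = cluster_topographies(seq, labels, k=model.k)
        return {
            "topography": topo,
            "entropy": cluster_entropy(topo.fractions).H,
            "n_avalanches": seq.n_patterns,
            "n_unique": uniq.shape[0],
        }

    thresholds = list(thresholds)
    ref = run_one(reference_threshold)
    out: dict[float, dict] = {}
    for th in thresholds:
        res = run_one(th) if th != reference_threshold else ref
        if res is None or ref is None:
            out[th] = {"entropy": None, "correlation_to_reference": None,
                       "n_avalanches": 0 if res is None else res["n_avalanches"]}
            continue
        _, _, avg_max = match_clusterings(res["topography"], ref["topography"])
        out[th] = {
            "entropy": res["entropy"],
            "correlation_to_reference": avg_max,
            "n_avalanches": res["n_avalanches"],
            "n_unique": res["n_unique"],
        }
    return out
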