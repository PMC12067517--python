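"""Neuronal avalanche extraction from region x time signals.

The pipeline entry point: each region's signal is z-scored over the full
recording, binarised at a fixed z-threshold (default 3 SD, strictly greater,
absolute value by default), and avalanches are defined as maximal runs of
samples during which at least one region is supra-threshold. Each avalanche
is summarised by its *pattern*: the binary vector over regions marking which
regions were recruited at any moment of the avalanche (spatial OR, internal
timing discarded). Unique patterns feed the embedding stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import (
    AvalancheInterval,
    BinaryRaster,
    PatternSequence,
    SignalSet,
)

__all__ = [
    "ConstantSignalError",
    "zscore",
    "binarize",
    "detect_avalanches",
    "extract_patterns",
    "unique_patterns",
    "avalanche_summary",
    "AvalancheSummary",
    "signals_to_patterns",
]


class ConstantSignalError(ValueError):
    """Raised when a region's signal has zero variance and cannot be z-scored."""


def zscore(signals: SignalSet) -> SignalSet:
    """Standardise each region's signal to mean 0, SD 1.

    Uses the population SD (divide by T). Idempotent within numerical
    precision: z-scoring an already standardised signal leaves it unchanged.

    Raises
    ------
    ConstantSignalError
        If any region has zero variance; the message names the region.
    """
    x = signals.values
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)  # ddof=0, population SD
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        bad = signals.region_labels[flat[0]]
        raise ConstantSignalError(
            f"region '{bad}' has constant signal (zero variance); cannot z-score"
        )
    return SignalSet(
        values=(x - mu) / sd,
        region_labels=signals.region_labels,
        sampling_rate=signals.sampling_rate,
        subject_id=signals.subject_id,
    )


def binarize(z: SignalSet, threshold: float = 3.0, mode: str = "absolute") -> BinaryRaster:
    """Threshold z-scored signals into a binary raster.

    ``active[r, t] = 1`` iff ``|z[r, t]| > threshold`` (absolute mode) or
    ``z[r, t] > threshold`` (positive mode). The comparison is strictly
    greater: a value exactly at the threshold is inactive.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    if mode == "absolute":
        active = np.abs(z.values) > threshold
    elif mode == "positive":
        active = z.values > threshold
    else:
        raise ValueError("mode must be 'absolute' or 'positive'")
    return BinaryRaster(
        active=active.astype(np.uint8),
        threshold=threshold,
        mode=mode,
        region_labels=z.region_labels,
        subject_id=z.subject_id,
    )


def detect_avalanches(raster: BinaryRaster) -> list[AvalancheInterval]:
    """Maximal runs of samples with at least one active region.

    An avalanche starts when at least one region is above threshold and ends
    when no region is above threshold; runs touching either end of the
    recording are included. Intervals are half-open ``[start, end)``.
    """
    any_active = raster.active.any(axis=0)
    if not any_active.any():
        return []
    padded = np.concatenate(([False], any_active, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return [
        AvalancheInterval(int(s), int(e), raster.subject_id)
        for s, e in zip(starts, ends)
    ]


def extract_patterns(
    raster: BinaryRaster, intervals: list[AvalancheInterval]
) -> PatternSequence:
    """Vectorise each avalanche: pattern[r] = 1 iff region r was active at
    one or more samples of the interval (logical OR over columns)."""
    t_total = raster.n_samples
    pats = np.zeros((len(intervals), raster.n_regions), dtype=np.uint8)
    for i, iv in enumerate(intervals):
        if iv.end > t_total:
            raise ValueError(
                f"interval [{iv.start}, {iv.end}) exceeds raster length {t_total}"
            )
        cols = raster.active[:, iv.start : iv.end]
        if not cols.any(axis=0).all():
            raise ValueError(
                f"interval [{iv.start}, {iv.end}) contains silent columns; "
                "not a valid avalanche for this raster"
            )
        pats[i] = cols.any(axis=1)
    return PatternSequence(
        patterns=pats,
        intervals=list(intervals),
        subject_ids=[iv.subject_id for iv in intervals],
        region_labels=raster.region_labels,
    )


def unique_patterns(
    seq: PatternSequence, scope: str = "pooled"
) -> tuple[np.ndarray, np.ndarray]:
    """Deduplicate avalanche patterns (exact binary equality).

    Returns ``(U x N unique matrix, occurrence index)`` where
    ``unique[index[p]] == seq.patterns[p]`` for every original pattern p.
    Unique rows are ordered by first occurrence. ``scope='pooled'`` dedupes
    across all subjects (the default, matching the pooled concatenation fed
    to the embedding); ``scope='per-subject'`` restarts the dedup within each
    subject, returning a stacked matrix and a global index.
    """
    if seq.n_patterns == 0:
        raise ValueError("empty pattern sequence")
    if scope == "pooled":
        return _unique_rows_first_occurrence(seq.patterns)
    if scope == "per-subject":
        blocks: list[np.ndarray] = []
        index = np.empty(seq.n_patterns, dtype=int)
        offset = 0
        for _, rows in seq.split_by_subject().items():
            u, idx = _unique_rows_first_occurrence(seq.patterns[rows])
            blocks.append(u)
            index[rows] = idx + offset
            offset += u.shape[0]
        return np.vstack(blocks), index
    raise ValueError("scope must be 'pooled' or 'per-subject'")


def _unique_rows_first_occurrence(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    _, first, inverse = np.unique(
        x, axis=0, return_index=True, return_inverse=True
    )
    inverse = np.asarray(inverse).ravel()
    order = np.argsort(first)  # restore first-occurrence order
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    return x[np.sort(first)], rank[inverse]


@dataclass(frozen=True)
class AvalancheSummary:
    n_avalanches: int
    sizes: np.ndarray  # regions recruited per avalanche
    durations: np.ndarray  # samples per avalanche
    fraction_time_active: float  # fraction of samples inside avalanches
    n_samples: int


def avalanche_summary(
    raster: BinaryRaster, intervals: list[AvalancheInterval]
) -> AvalancheSummary:
    """Count/size/duration distributions and the fraction of time points that
    fall inside avalanches (sparse regimes sit well below 0.05)."""
    durations = np.array([iv.duration for iv in intervals], dtype=int)
    sizes = np.array(
        [
            int(raster.active[:, iv.start : iv.end].any(axis=1).sum())
            for iv in intervals
        ],
        dtype=int,
    )
    return AvalancheSummary(
        n_avalanches=len(intervals),
        sizes=sizes,
        durations=durations,
        fraction_time_active=float(durations.sum()) / raster.n_samples,
        n_samples=raster.n_samples,
    )


def signals_to_patterns(
    signals: SignalSet, threshold: float = 3.0, mode: str = "absolute"
) -> PatternSequence:
    """Convenience composition: z-score -> binarise -> detect -> vectorise."""
    raster = binarize(zscore(signals), threshold=threshold, mode=mode)
    return extract_patterns(raster, detect_avalanches(raster))
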