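"""Core in-memory containers shared across the pipeline.

A :class:`SignalSet` holds one subject's region x time source signals; a
:class:`BinaryRaster` the thresholded version; :class:`AvalancheInterval` a
half-open epoch during which at least one region is supra-threshold; and a
:class:`PatternSequence` the chronological sequence of binary avalanche
patterns (one length-N vector per avalanche, 1 where a region was recruited
at any moment of the avalanche).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as _importlib_resources

import numpy as np

__all__ = [
    "SignalSet",
    "BinaryRaster",
    "AvalancheInterval",
    "PatternSequence",
    "default_region_labels",
]


def default_region_labels(n_regions: int = 90) -> list[str]:
    """Region labels for the default 90-region anatomical parcellation.

    For ``n_regions == 90`` the bundled AAL labels (78 cortical + 12
    subcortical) are returned; otherwise generic ``R000``-style labels.
    """
    if n_regions == 90:
        text = (
            _importlib_resources.files("avalanchestates.resources")
            .joinpath("aal90.txt")
            .read_text()
        )
        labels = [ln.strip() for ln in text.splitlines() if ln.strip()]
        assert len(labels) == 90
        return labels
    return [f"R{i:03d}" for i in range(n_regions)]


@dataclass
class SignalSet:
    """Region x time real-valued signals for one subject.

    Parameters
    ----------
    values : (N, T) float array
        One row per region.
    region_labels : list of str
        Unique region names, length N.
    sampling_rate : float
        Samples per second.
    subject_id : str
    """

    values: np.ndarray
    region_labels: list[str]
    sampling_rate: float
    subject_id: str = "subject"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D region x time matrix")
        n, t = self.values.shape
        if n < 1 or t < 2:
            raise ValueError("need at least 1 region and 2 samples")
        if np.isnan(self.values).any():
            raise ValueError("values contain missing entries")
        self.region_labels = [str(r) for r in self.region_labels]
        if len(self.region_labels) != n:
            raise ValueError(
                f"{len(self.region_labels)} labels for {n} regions"
            )
        if len(set(self.region_labels)) != n:
            raise ValueError("region labels must be unique")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class BinaryRaster:
    """Thresholded signals: ``active[r, t] = 1`` iff region r exceeds the
    z-threshold at sample t (strictly greater; absolute or positive mode)."""

    active: np.ndarray
    threshold: float
    mode: str = "absolute"
    region_labels: list[str] | None = None
    subject_id: str = "subject"

    def __post_init__(self):
        self.active = np.asarray(self.active)
        if self.active.ndim != 2:
            raise ValueError("active must be 2-D")
        vals = np.unique(self.active)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("raster entries must be 0/1")
        self.active = self.active.astype(np.uint8)
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")
        if self.mode not in ("absolute", "positive"):
            raise ValueError("mode must be 'absolute' or 'positive'")

    @property
    def n_regions(self) -> int:
        return self.active.shape[0]

    @property
    def n_samples(self) -> int:
        return self.active.shape[1]


@dataclass(frozen=True)
class AvalancheInterval:
    """Half-open sample interval [start, end) of one avalanche (0-based)."""

    start: int
    end: int
    subject_id: str = "subject"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def duration(self) -> int:
        return self.end - self.start


@dataclass
class PatternSequence:
    """Chronologically ordered binary avalanche patterns.

    ``patterns`` is a (P, N) uint8 matrix, row p marking the regions recruited
    by the p-th avalanche; ``intervals`` and ``subject_ids`` run parallel to
    the rows. Within each subject the rows are in temporal order.
    """

    patterns: np.ndarray
    intervals: list[AvalancheInterval]
    subject_ids: list[str] = field(default=None)
    region_labels: list[str] | None = None

    def __post_init__(self):
        self.patterns = np.asarray(self.patterns, dtype=np.uint8)
        if self.patterns.ndim != 2:
            raise ValueError("patterns must be 2-D (avalanches x regions)")
        if self.subject_ids is None:
            self.subject_ids = [iv.subject_id for iv in self.intervals]
        p = self.patterns.shape[0]
        if len(self.intervals) != p or len(self.subject_ids) != p:
            raise ValueError("patterns, intervals and subject_ids must align")
        if p and not np.all(self.patterns.sum(axis=1) >= 1):
            raise ValueError("every pattern must recruit at least one region")

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_regions(self) -> int:
        return self.patterns.shape[1]

    def subjects(self) -> list[str]:
        """Distinct subject ids in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.subject_ids:
            seen.setdefault(s, None)
        return list(seen)

    def split_by_subject(self) -> dict[str, np.ndarray]:
        """Row indices of each subject's avalanches, chronological order."""
        ids = np.asarray(self.subject_ids)
        return {s: np.flatnonzero(ids == s) for s in self.subjects()}

    @classmethod
    def concatenate(cls, sequences: list["PatternSequence"]) -> "PatternSequence":
        if not sequences:
            raise ValueError("nothing to concatenate")
        n = {s.n_regions for s in sequences}
        if len(n) != 1:
            raise ValueError("sequences have differing region counts")
        return cls(
            patterns=np.vstack([s.patterns for s in sequences]),
            intervals=[iv for s in sequences for iv in s.intervals],
            subject_ids=[sid for s in sequences for sid in s.subject_ids],
            region_labels=sequences[0].region_labels,
        )
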