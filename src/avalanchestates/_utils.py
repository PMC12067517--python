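"""Small shared helpers: knee detection, seed handling, validation."""

from __future__ import annotations

import numpy as np


def as_rng(seed) -> np.random.Generator:
    """Coerce an int, SeedSequence, Generator or None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(master_seed: int, n: int) -> list[np.random.SeedSequence]:
    """Derive ``n`` independent child seed sequences from one master seed.

    A fixed splitting rule (SeedSequence.spawn) keeps per-subject / per-stage
    streams reproducible and statistically independent.
    """
    return np.random.SeedSequence(master_seed).spawn(n)


def knee_point(x: np.ndarray, y: np.ndarray) -> int:
    """Index of the knee of a curve by the maximum-distance-to-chord rule.

    The chord joins the first and last point; the knee is the point with the
    largest perpendicular distance to it. Returns the index into ``x``/``y``.
    Ties break toward the smaller index; a flat curve returns 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("knee_point needs two arrays of equal length >= 2")
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    if norm == 0:
        return 0
    pts = np.column_stack([x, y]) - p0
    # perpendicular distance via 2-D cross product
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / norm
    return int(np.argmax(dist))


def check_finite(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a
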