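"""Avalanche extraction: z-scoring, binarisation, detection, patterns."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from avalanchestates.avalanche import (
    ConstantSignalError,
    avalanche_summary,
    binarize,
    detect_avalanches,
    extract_patterns,
    signals_to_patterns,
    unique_patterns,
    zscore,
)
from avalanchestates.containers import BinaryRaster, PatternSequence, SignalSet


def make_signals(values, fs=256.0, sid="s0"):
    values = np.asarray(values, dtype=float)
    return SignalSet(values, [f"R{i}" for i in range(values.shape[0])], fs, sid)


class TestZscore:
    def test_hand_computed_row(self):
        z = zscore(make_signals([[1.0, 2.0, 3.0]]))
        assert np.allclose(z.values, [[-1.224744871, 0.0, 1.224744871]], atol=1e-8)

    def test_moments_and_idempotence(self, rng):
        sig = make_signals(rng.normal(5.0, 3.0, size=(4, 500)))
        z = zscore(sig)
        assert np.allclose(z.values.mean(axis=1), 0.0, atol=1e-10)
        assert np.allclose(z.values.std(axis=1), 1.0, atol=1e-10)
        zz = zscore(z)
        assert np.allclose(zz.values, z.values, atol=1e-10)

    def test_constant_region_error_names_region(self):
        with pytest.raises(ConstantSignalError, match="R1"):
            zscore(make_signals([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]))

    def test_affine_invariance_of_detection(self, rng):
        """detect . binarize . zscore is invariant to per-region affine maps."""
        x = rng.standard_normal((5, 400))
        scale = rng.uniform(0.5, 20.0, size=(5, 1))
        offset = rng.uniform(-30, 30, size=(5, 1))
        a = binarize(zscore(make_signals(x)), 2.0)
        b = binarize(zscore(make_signals(x * scale + offset)), 2.0)
        assert np.array_equal(a.active, b.active)


class TestBinarize:
    @pytest.mark.parametrize(
        "mode,expected",
        [("absolute", [0, 1, 1, 0]), ("positive", [0, 1, 0, 0])],
    )
    def test_threshold_modes(self, mode, expected):
        z = make_signals([[0.0, 3.1, -3.5, 2.9]])
        raster = binarize(z, threshold=3.0, mode=mode)
        assert raster.active.tolist() == [expected]

    def test_exact_threshold_is_inactive(self):
        raster = binarize(make_signals([[3.0, -3.0]]), threshold=3.0)
        assert raster.active.sum() == 0

    def test_gaussian_tail_rate(self):
        """Supra-threshold fraction of N(0,1) noise matches the Gaussian tail."""
        from scipy.stats import norm

        rng = np.random.default_rng(99)
        t_len = 10**6
        sig = make_signals(rng.standard_normal((3, t_len)))
        raster = binarize(zscore(sig), threshold=3.0, mode="positive")
        p = norm.sf(3.0)  # 0.00135
        se = np.sqrt(p * (1 - p) / t_len)
        frac = raster.active.mean(axis=1)
        assert np.all(np.abs(frac - p) <= 3 * se)


class TestDetect:
    def test_interval_example(self):
        active = np.array([[0, 1, 1, 0, 1, 0]], dtype=np.uint8)
        ivs = detect_avalanches(BinaryRaster(active, 3.0))
        assert [(iv.start, iv.end) for iv in ivs] == [(1, 3), (4, 5)]

    def test_empty_raster(self):
        assert detect_avalanches(BinaryRaster(np.zeros((3, 10)), 3.0)) == []

    def test_boundary_runs_included(self):
        active = np.array([[1, 1, 0, 0, 1]], dtype=np.uint8)
        ivs = detect_avalanches(BinaryRaster(active, 3.0))
        assert [(iv.start, iv.end) for iv in ivs] == [(0, 2), (4, 5)]

    @settings(max_examples=50, deadline=None)
    @given(
        hnp.arrays(np.uint8, hnp.array_shapes(min_dims=2, max_dims=2,
                                              min_side=1, max_side=30),
                   elements=st.integers(0, 1))
    )
    def test_matches_bruteforce_column_scan(self, active):
        """Detection equals an exhaustive per-column scan oracle, and the
        union of intervals covers exactly the active columns."""
        raster = BinaryRaster(active, 3.0)
        ivs = detect_avalanches(raster)
        # brute-force oracle
        expected = []
        start = None
        col = active.any(axis=0)
        for t, on in enumerate(col):
            if on and start is None:
                start = t
            if not on and start is not None:
                expected.append((start, t))
                start = None
        if start is not None:
            expected.append((start, len(col)))
        assert [(iv.start, iv.end) for iv in ivs] == expected
        covered = np.zeros(active.shape[1], dtype=bool)
        for iv in ivs:
            covered[iv.start:iv.end] = True
        assert np.array_equal(covered, col)


class TestPatterns:
    def test_or_semantics(self):
        active = np.array(
            [[0, 1, 0, 0], [0, 0, 0, 0], [0, 0, 1, 0]], dtype=np.uint8
        )
        raster = BinaryRaster(active, 3.0)
        seq = extract_patterns(raster, detect_avalanches(raster))
        assert seq.patterns.tolist() == [[1, 0, 1]]

    def test_single_column_avalanche_equals_column(self):
        active = np.array([[0, 1, 0], [0, 1, 0], [0, 0, 0]], dtype=np.uint8)
        raster = BinaryRaster(active, 3.0)
        seq = extract_patterns(raster, detect_avalanches(raster))
        assert seq.patterns.tolist() == [[1, 1, 0]]

    def test_invalid_interval_rejected(self):
        from avalanchestates.containers import AvalancheInterval

        raster = BinaryRaster(np.array([[1, 0, 1]], dtype=np.uint8), 3.0)
        with pytest.raises(ValueError, match="silent columns"):
            extract_patterns(raster, [AvalancheInterval(0, 3)])


class TestUniquePatterns:
    def test_dedup_and_index_map(self):
        seq = _pattern_seq([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]])
        uniq, idx = unique_patterns(seq)
        assert uniq.shape[0] == 2
        assert idx.tolist() == [0, 0, 1]
        assert np.array_equal(uniq[idx], seq.patterns)

    def test_all_distinct_identity_map(self):
        seq = _pattern_seq([[1, 0], [0, 1], [1, 1]])
        uniq, idx = unique_patterns(seq)
        assert uniq.shape[0] == 3 and idx.tolist() == [0, 1, 2]

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**30))
    def test_matches_sort_based_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pats = (rng.random((200, 10)) < 0.3).astype(np.uint8)
        pats[pats.sum(axis=1) == 0, 0] = 1  # patterns must be non-empty
        seq = _pattern_seq(pats.tolist())
        uniq, idx = unique_patterns(seq)
        oracle_u = len({tuple(row) for row in pats.tolist()})
        assert uniq.shape[0] == oracle_u
        assert np.array_equal(uniq[idx], seq.patterns)

    def test_per_subject_scope(self):
        seq = _pattern_seq([[1, 0], [1, 0], [1, 0]], subjects=["a", "a", "b"])
        uniq, idx = unique_patterns(seq, scope="per-subject")
        assert uniq.shape[0] == 2  # one per subject
        assert idx.tolist() == [0, 0, 1]


class TestSummary:
    def test_counts_durations_fraction(self):
        active = np.array([[0, 1, 1, 0, 1, 0]], dtype=np.uint8)
        raster = BinaryRaster(active, 3.0)
        s = avalanche_summary(raster, detect_avalanches(raster))
        assert s.n_avalanches == 2
        assert sorted(s.durations.tolist()) == [1, 2]
        assert s.fraction_time_active == pytest.approx(0.5)

    def test_empty(self):
        raster = BinaryRaster(np.zeros((2, 8)), 3.0)
        s = avalanche_summary(raster, [])
        assert s.n_avalanches == 0 and s.fraction_time_active == 0.0


def test_pipeline_recovers_ground_truth_exactly(small_cohort):
    """Fixture-mode simulation: detector output equals planted intervals and
    planted recruited-region patterns, per subject."""
    signals, truth = small_cohort
    for sig in signals:
        seq = signals_to_patterns(sig)
        gt_ivs = truth.avalanche_intervals[sig.subject_id]
        assert [(iv.start, iv.end) for iv in seq.intervals] == [
            (iv.start, iv.end) for iv in gt_ivs
        ]


def _pattern_seq(patterns, subjects=None):
    from avalanchestates.containers import AvalancheInterval

    patterns = np.asarray(patterns, dtype=np.uint8)
    n = patterns.shape[0]
    subjects = subjects or ["s0"] * n
    ivs = []
    pos = {}
    for i in range(n):
        start = pos.get(subjects[i], 0)
        ivs.append(AvalancheInterval(start, start + 1, subjects[i]))
        pos[subjects[i]] = start + 2
    return PatternSequence(patterns, ivs, subjects)
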