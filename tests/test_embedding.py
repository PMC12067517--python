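"""Diffusion embedding: every stage against a literal-formula oracle."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from avalanchestates.embedding import (
    DegenerateBandwidthError,
    EmbeddingParams,
    alpha_decay_kernel,
    cosine_distance_matrix,
    markov_normalize,
    mds_embed,
    pca_reduce,
    phate,
    potential_distances,
    select_diffusion_time,
    von_neumann_entropy,
)


class TestPCA:
    def test_rank_one_data(self, rng):
        direction = np.array([1.0, 2.0, -1.0])
        x = rng.standard_normal((40, 1)) * direction
        scores, evr = pca_reduce(x, 1)
        assert evr[0] == pytest.approx(1.0, abs=1e-10)

    def test_variance_ratios_sum_to_one(self, rng):
        x = rng.standard_normal((30, 6))
        _, evr = pca_reduce(x, 6)
        assert evr.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(evr) <= 1e-12)  # non-increasing

    def test_matches_covariance_eigendecomposition(self, rng):
        """Scores equal the centred projection onto covariance eigenvectors
        up to per-component sign."""
        x = rng.standard_normal((50, 10))
        scores, evr = pca_reduce(x, 4)
        xc = x - x.mean(axis=0)
        lam, vec = np.linalg.eigh(xc.T @ xc / x.shape[0])
        order = np.argsort(lam)[::-1][:4]
        oracle = xc @ vec[:, order]
        for c in range(4):
            assert (
                np.allclose(scores[:, c], oracle[:, c], atol=1e-8)
                or np.allclose(scores[:, c], -oracle[:, c], atol=1e-8)
            )

    def test_rank_deficiency_warns(self, rng):
        x = np.tile(rng.standard_normal((20, 1)), (1, 5))
        with pytest.warns(RuntimeWarning, match="rank"):
            scores, _ = pca_reduce(x, 3)
        assert scores.shape[1] == 1


class TestCosineDistances:
    def test_closed_form_cases(self):
        x = np.array([[1.0, 0.0], [2.0, 0.0], [0.0, 3.0], [-1.0, 0.0]])
        d = cosine_distance_matrix(x)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)  # parallel
        assert d[0, 2] == pytest.approx(1.0, abs=1e-12)  # orthogonal
        assert d[0, 3] == pytest.approx(2.0, abs=1e-12)  # antiparallel

    def test_matches_double_loop_oracle(self, rng):
        x = rng.standard_normal((20, 5))
        d = cosine_distance_matrix(x)
        for i in range(20):
            for j in range(20):
                expect = 1.0 - x[i] @ x[j] / (
                    np.linalg.norm(x[i]) * np.linalg.norm(x[j])
                )
                assert abs(d[i, j] - expect) <= 1e-12

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cosine_distance_matrix(np.array([[0.0, 0.0], [1.0, 1.0]]))


class TestAlphaDecayKernel:
    def test_matches_literal_formula_oracle(self, rng):
        pts = rng.standard_normal((10, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        for knn, alpha in [(2, 1.0), (3, 2.0)]:
            k = alpha_decay_kernel(d, knn=knn, alpha=alpha)
            eps = np.array(
                [np.sort(np.delete(d[i], i))[knn - 1] for i in range(10)]
            )
            for i in range(10):
                for j in range(10):
                    expect = 0.5 * (
                        np.exp(-((d[i, j] / eps[i]) ** alpha))
                        + np.exp(-((d[i, j] / eps[j]) ** alpha))
                    )
                    if i == j:
                        expect = 1.0
                    assert abs(k[i, j] - expect) <= 1e-12
            assert np.allclose(k, k.T, atol=1e-15)
            assert np.all((k > 0) & (k <= 1.0))

    def test_bandwidth_distance_gives_inverse_e(self):
        # 3 collinear points at 0, 1, 2: for knn=1 each end point has eps=1
        d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        k = alpha_decay_kernel(d, knn=1, alpha=1.0)
        assert k[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_duplicate_points_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(DegenerateBandwidthError):
            alpha_decay_kernel(d, knn=1)


class TestDiffusionOperator:
    def test_row_normalisation(self):
        k = np.array([[1.0, 1.0], [1.0, 1.0]])
        p = markov_normalize(k)
        assert np.allclose(p, 0.5)

    def test_rows_sum_to_one_under_powering(self, rng):
        k = rng.random((15, 15)) + 1e-3
        k = 0.5 * (k + k.T)
        p = markov_normalize(k)
        for t in (1, 2, 5, 10, 25):
            pt = np.linalg.matrix_power(p, t)
            assert np.allclose(pt.sum(axis=1), 1.0, atol=1e-10)

    def test_power_matches_repeated_application(self, rng):
        k = rng.random((8, 8)) + 0.1
        p = markov_normalize(k)
        p2 = np.linalg.matrix_power(p, 2)
        oracle = np.vstack([p.T @ (p.T @ e) for e in np.eye(8)])
        assert np.allclose(p2, oracle, atol=1e-12)


class TestDiffusionTime:
    def test_identity_falls_back_with_warning(self):
        with pytest.warns(RuntimeWarning, match="flat"):
            t = select_diffusion_time(np.eye(6), t_max=20)
        assert t == 1

    def test_two_blob_knee_matches_curve_scan(self, rng):
        pts = np.vstack(
            [rng.normal(0, 0.2, (15, 2)), rng.normal(5, 0.2, (15, 2))]
        )
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        p = markov_normalize(alpha_decay_kernel(d, knn=3))
        t = select_diffusion_time(p, t_max=50)
        vne = von_neumann_entropy(p, t_max=50)
        # knee oracle: max perpendicular distance to the end-to-end chord
        ts = np.arange(1, 51, dtype=float)
        chord = np.array([ts[-1] - ts[0], vne[-1] - vne[0]])
        rel = np.column_stack([ts - ts[0], vne - vne[0]])
        dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
        assert t == int(ts[np.argmax(dist)])

    def test_deterministic(self, rng):
        k = rng.random((12, 12)) + 0.05
        p = markov_normalize(0.5 * (k + k.T))
        assert select_diffusion_time(p) == select_diffusion_time(p)


class TestPotentialDistances:
    def test_three_state_chain_hand_computed(self):
        p = np.array([[0.6, 0.3, 0.1], [0.2, 0.5, 0.3], [0.1, 0.4, 0.5]])
        d = potential_distances(p, t=1)
        for i in range(3):
            for j in range(3):
                expect = np.linalg.norm(np.log(p[i]) - np.log(p[j]))
                assert abs(d[i, j] - expect) <= 1e-10

    def test_identical_rows_give_zero(self):
        p = np.array([[0.5, 0.5], [0.5, 0.5]])
        assert np.allclose(potential_distances(p, 1), 0.0, atol=1e-12)

    def test_triangle_inequality(self, rng):
        k = rng.random((12, 12)) + 0.01
        p = markov_normalize(0.5 * (k + k.T))
        d = potential_distances(p, t=2)
        n = d.shape[0]
        for _ in range(50):
            i, j, m = rng.integers(n, size=3)
            assert d[i, j] <= d[i, m] + d[m, j] + 1e-9


class TestMDS:
    def test_square_recovered_within_one_percent(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        coords, stress = mds_embed(d, n_dims=2, seed=0)
        rec = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        mask = d > 0
        assert np.all(np.abs(rec[mask] - d[mask]) / d[mask] < 0.01)

    def test_full_dimensional_embedding_has_negligible_stress(self, rng):
        pts = rng.standard_normal((8, 7))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        _, stress = mds_embed(d, n_dims=7, seed=0)
        total = (d**2).sum() / 2
        assert stress / total < 1e-6

    def test_deterministic_given_seed(self, rng):
        d = np.abs(rng.standard_normal((10, 10)))
        d = 0.5 * (d + d.T)
        np.fill_diagonal(d, 0)
        a, _ = mds_embed(d, 3, seed=5)
        b, _ = mds_embed(d, 3, seed=5)
        assert np.array_equal(a, b)


class TestFullEmbedding:
    def test_separated_families_stay_separated(self, rng):
        """Two far-separated pattern families: between-family embedding
        distances exceed within-family distances for >= 95% of pairs."""
        a = np.zeros((30, 20), dtype=np.uint8)
        b = np.zeros((30, 20), dtype=np.uint8)
        a[:, :8] = rng.random((30, 8)) < 0.8
        b[:, 12:] = rng.random((30, 8)) < 0.8
        x = np.unique(np.vstack([a, b]), axis=0)
        x = x[x.sum(axis=1) > 0]
        n_a = (x[:, :8].sum(axis=1) > 0).sum()
        emb = phate(x.astype(float), EmbeddingParams(n_pca=5, knn=5))
        c = emb.coords
        d = np.sqrt(((c[:, None] - c[None]) ** 2).sum(-1))
        within = np.concatenate(
            [d[:n_a, :n_a][np.triu_indices(n_a, 1)],
             d[n_a:, n_a:][np.triu_indices(len(x) - n_a, 1)]]
        )
        between = d[:n_a, n_a:].ravel()
        thresh = np.median(within)
        assert (between > thresh).mean() >= 0.95

    def test_row_permutation_equivariance(self, rng):
        x = (rng.random((40, 12)) < 0.4).astype(float)
        x = np.unique(x, axis=0)
        x = x[x.sum(axis=1) > 0]
        params = EmbeddingParams(n_pca=4, knn=4, t=3)
        emb = phate(x, params)
        perm = rng.permutation(x.shape[0])
        emb_p = phate(x[perm], params)
        # same pairwise geometry up to the permutation
        d0 = np.sqrt(((emb.coords[:, None] - emb.coords[None]) ** 2).sum(-1))
        d1 = np.sqrt(((emb_p.coords[:, None] - emb_p.coords[None]) ** 2).sum(-1))
        assert np.allclose(d1, d0[np.ix_(perm, perm)], atol=1e-6)

    def test_trajectory_order_preserved(self, rng):
        """Points along a noisy 1-D curve: the first embedding axis orders
        them like the generating parameter (|Spearman| >= 0.9)."""
        n = 120
        s = np.linspace(0, 1, n)
        x = np.column_stack(
            [np.cos(2.5 * s), np.sin(2.5 * s), 2.0 * s, s**2, np.sqrt(1 + s)]
        )
        x += 0.01 * rng.standard_normal(x.shape)
        emb = phate(x, EmbeddingParams(n_pca=5, knn=10, n_dims=2))
        rho = spearmanr(s, emb.coords[:, 0]).statistic
        assert abs(rho) >= 0.9

    def test_pca_method_returns_pca_scores(self, rng):
        x = (rng.random((30, 10)) < 0.5).astype(float)
        x = np.unique(x, axis=0)
        x = x[x.sum(axis=1) > 0]
        emb = phate(x, EmbeddingParams(n_pca=5, n_dims=3, method="pca"))
        scores, _ = pca_reduce(x, 5)
        assert np.allclose(emb.coords, scores[:, :3], atol=1e-10)
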