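"""Standardization and PCA: oracle equivalence, conservation, determinism."""

import numpy as np
import pytest

from oracles import brute_force_pca_scores
from pcaplace import (
    DegenerateInputError,
    SimConfig,
    load_space,
    pca_joint,
    pca_reference,
    save_space,
    simulate_panel,
    standardize,
)


def _align_signs(A, B):
    """Flip columns of B to match A's signs (PCA signs are arbitrary)."""
    signs = np.sign(np.sum(A * B, axis=0))
    signs[signs == 0] = 1.0
    return B * signs


class TestStandardize:
    def test_center_only_basics(self):
        X, means, scales = standardize(np.array([[0.0], [1.0], [2.0]]))
        assert np.allclose(X.ravel(), [-1, 0, 1])
        assert means[0] == 1.0 and scales[0] == 1.0

    def test_constant_column_gets_unit_scale(self):
        X, _, scales = standardize(np.full((3, 1), 2.0), mode="center_scale")
        assert np.allclose(X, 0.0)
        assert scales[0] == 1.0

    def test_missing_imputed_with_column_mean(self):
        g = np.array([[0.0, np.nan], [2.0, 1.0]])
        X, means, _ = standardize(g)
        assert means[1] == 1.0
        assert X[0, 1] == 0.0  # imputed to the mean, then centered

    def test_idempotent_with_returned_stats(self, rng):
        g = rng.integers(0, 3, size=(20, 30)).astype(float)
        X1, means, scales = standardize(g, mode="center_scale")
        X2, _, _ = standardize(X1 * scales + means, mode="center_scale", means=means, scales=scales)
        assert np.allclose(X1, X2, atol=1e-12)

    def test_all_missing_column_rejected(self):
        g = np.array([[np.nan], [np.nan]])
        with pytest.raises(DegenerateInputError):
            standardize(g)

    def test_supplied_stats_override(self, rng):
        g = rng.integers(0, 3, size=(5, 4)).astype(float)
        means = np.full(4, 1.0)
        X, m, _ = standardize(g, means=means)
        assert np.array_equal(m, means)
        assert np.allclose(X, g - 1.0)


class TestReferencePCA:
    def test_matches_eigendecomposition_oracle(self, rng):
        """Scores from the SVD route equal a dense covariance
        eigendecomposition on random matrices."""
        cfg = SimConfig(n_pops=2, n_per_pop=10, L=50, Fst=0.2, seed=4)
        panel, _ = simulate_panel(cfg)
        space = pca_reference(panel, K=5)
        X, _, _ = standardize(panel.genotypes)
        oracle = _align_signs(space.Y, brute_force_pca_scores(X, 5))
        assert np.allclose(space.Y, oracle, atol=1e-8)

    def test_variance_conservation(self, small_panel):
        """Sum of all eigenvalues equals the standardized matrix's total
        variance."""
        panel, _ = small_panel
        n = panel.n_samples
        space = pca_reference(panel, K=n - 1)
        X, _, _ = standardize(panel.genotypes)
        total = np.sum(X * X) / (n - 1)
        assert np.sum(space.eigenvalues) == pytest.approx(total, rel=1e-8)

    def test_scores_orthogonal_and_eigenvalues_sorted(self, small_space):
        G = small_space.Y.T @ small_space.Y
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() <= 1e-6 * np.diag(G).max()
        assert np.all(np.diff(small_space.eigenvalues) <= 1e-12)

    def test_population_separation_on_pc1(self):
        """Two strongly differentiated populations separate on PC1 with a
        between-cluster gap exceeding within-cluster spread (silhouette-like
        check)."""
        cfg = SimConfig(n_pops=2, n_per_pop=25, L=500, Fst=0.3, seed=9)
        panel, _ = simulate_panel(cfg)
        space = pca_reference(panel, K=2)
        pc1 = space.Y[:, 0]
        a, b = pc1[:25], pc1[25:]
        gap = abs(a.mean() - b.mean())
        assert gap > a.std() + b.std()

    def test_permutation_equivariance(self, rng):
        cfg = SimConfig(n_pops=2, n_per_pop=8, L=60, Fst=0.2, seed=6)
        panel, _ = simulate_panel(cfg)
        space = pca_reference(panel, K=3)
        perm = rng.permutation(panel.n_samples)
        panel.genotypes = panel.genotypes[perm]
        panel.sample_ids = panel.sample_ids[perm]
        panel.population = panel.population[perm]
        space_p = pca_reference(panel, K=3)
        assert np.allclose(space_p.Y, space.Y[perm], atol=1e-8)

    def test_k_too_large_rejected(self, small_panel):
        panel, _ = small_panel
        with pytest.raises(ValueError):
            pca_reference(panel, K=panel.n_samples)


class TestJointPCA:
    def test_duplicate_row_gets_identical_scores(self, small_panel):
        panel, _ = small_panel
        res = pca_joint(panel.genotypes, panel.genotypes[7], K_prime=10)
        assert np.allclose(res.x_study, res.X_ref[7], atol=1e-8)

    def test_matches_gram_matrix_oracle(self, rng):
        """Tiny instance: scores agree with an eigendecomposition of the
        (N+1)x(N+1) Gram matrix of the jointly standardized data."""
        panel_rows = rng.integers(0, 3, size=(3, 8)).astype(float)
        study = rng.integers(0, 3, size=8).astype(float)
        res = pca_joint(panel_rows, study, K_prime=2)
        X, _, _ = standardize(np.vstack([panel_rows, study]))
        gram = X @ X.T
        w, V = np.linalg.eigh(gram)
        order = np.argsort(w)[::-1][:2]
        oracle = V[:, order] * np.sqrt(np.maximum(w[order], 0))
        scores = np.vstack([res.X_ref, res.x_study])
        assert np.allclose(scores, _align_signs(scores, oracle), atol=1e-8)

    def test_site_permutation_invariance(self, rng, small_panel):
        panel, _ = small_panel
        g = panel.genotypes[:, :100]
        study = g[3]
        res = pca_joint(g, study, K_prime=5)
        perm = rng.permutation(100)
        res_p = pca_joint(g[:, perm], study[perm], K_prime=5)
        assert np.allclose(res_p.X_ref, res.X_ref, atol=1e-8)

    def test_all_missing_study_rejected(self, small_panel):
        panel, _ = small_panel
        with pytest.raises(DegenerateInputError):
            pca_joint(panel.genotypes, np.full(panel.n_sites, np.nan), K_prime=5)


class TestSpacePersistence:
    def test_round_trip(self, tmp_path, small_panel, small_space):
        panel, _ = small_panel
        prefix = tmp_path / "ws"
        save_space(small_space, prefix, sample_ids=panel.sample_ids)
        loaded, ids = load_space(prefix)
        assert np.allclose(loaded.Y, small_space.Y, rtol=1e-9)
        assert np.allclose(loaded.site_means, small_space.site_means, rtol=1e-9)
        assert np.allclose(loaded.eigenvalues, small_space.eigenvalues, rtol=1e-9)
        assert loaded.scaling_mode == small_space.scaling_mode
        assert list(ids) == list(panel.sample_ids)
        assert len(loaded.sites) == len(small_space.sites)
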