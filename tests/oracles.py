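"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the projection
Procrustes oracle optimizes the objective directly over a smooth
parametrization of the Stiefel manifold (plus mass random sampling), and
the Fst oracle is the standard Hudson two-population moment estimator.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def procrustes_objective_terms(X: np.ndarray, Y: np.ndarray):
    """Centered cross-products defining D(A) = trY - tr(A^T C)^2 / tr(A^T S A)
    (rho and b already profiled out for a fixed orthonormal-column A)."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    C = Xc.T @ Yc
    S = Xc.T @ Xc
    tr_y = float(np.sum(Yc * Yc))
    return C, S, tr_y


def d_of_stiefel(A: np.ndarray, C: np.ndarray, S: np.ndarray, tr_y: float) -> float:
    num = abs(float(np.sum(A * C)))  # |tr(A^T C)|; -A is also feasible
    den = float(np.einsum("ij,ik,kj->", A, S, A))
    if den <= 0:
        return tr_y
    return tr_y - num**2 / den


def best_random_stiefel_d(
    C: np.ndarray, S: np.ndarray, tr_y: float, n_draws: int, rng: np.random.Generator
) -> tuple[float, np.ndarray]:
    """Minimum D over random orthonormal-column maps (batched QR)."""
    k_prime, k = C.shape
    G = rng.standard_normal((n_draws, k_prime, k))
    Q = np.linalg.qr(G).Q  # batched reduced QR
    num = np.abs(np.einsum("nij,ij->n", Q, C))
    den = np.einsum("nij,ik,nkj->n", Q, S, Q)
    d = tr_y - num**2 / den
    i = int(np.argmin(d))
    return float(d[i]), Q[i]


def _polar_factor(M: np.ndarray) -> np.ndarray:
    """Smooth retraction onto the Stiefel manifold: A = M (M^T M)^{-1/2}."""
    w, V = np.linalg.eigh(M.T @ M)
    w = np.maximum(w, 1e-300)
    return M @ (V / np.sqrt(w)) @ V.T


def oracle_min_d(
    X: np.ndarray,
    Y: np.ndarray,
    n_draws: int = 10_000,
    n_restarts: int = 3,
    rng: np.random.Generator | None = None,
) -> float:
    """Best D found by 10^4 random valid transforms plus local optimization
    over the polar parametrization of the Stiefel manifold."""
    rng = rng or np.random.default_rng(0)
    C, S, tr_y = procrustes_objective_terms(X, Y)
    k_prime, k = C.shape

    d_best, A_best = best_random_stiefel_d(C, S, tr_y, n_draws, rng)

    def obj(flat: np.ndarray) -> float:
        M = flat.reshape(k_prime, k)
        if np.linalg.matrix_rank(M) < k:
            return tr_y
        return d_of_stiefel(_polar_factor(M), C, S, tr_y)

    starts = [A_best] + [rng.standard_normal((k_prime, k)) for _ in range(n_restarts)]
    for M0 in starts:
        res = minimize(obj, M0.ravel(), method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-16, "gtol": 1e-12})
        d_best = min(d_best, float(res.fun))
    return d_best


def hudson_fst(g1: np.ndarray, g2: np.ndarray) -> float:
    """Hudson's two-population Fst (ratio-of-averages moment estimator)
    from diploid genotype matrices (individuals × sites)."""
    n1, n2 = g1.shape[0] * 2, g2.shape[0] * 2
    p1 = np.nanmean(g1, axis=0) / 2.0
    p2 = np.nanmean(g2, axis=0) / 2.0
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    return float(num[keep].sum() / den[keep].sum())


def random_stiefel(k_prime: int, k: int, rng: np.random.Generator) -> np.ndarray:
    Q = np.linalg.qr(rng.standard_normal((k_prime, k))).Q
    return Q


def brute_force_pca_scores(X: np.ndarray, k: int) -> np.ndarray:
    """PCA scores via dense eigendecomposition of the covariance (independent
    of the SVD route): scores = centered data projected on top eigenvectors.
    Signs are aligned afterwards by the caller."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1][:k]
    return Xc @ V[:, order]
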