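"""Projection Procrustes analysis.

Given a source configuration X (N points in K' dimensions) and a target
configuration Y (the same N points in K dimensions, K <= K'), find the
orthonormal-column projection A (K'xK), isotropic scale rho > 0 and
translation b minimizing

    D = || rho * Xc A + 1 b^T  -  Y ||_F^2        subject to  A^T A = I.

For K' = K this is the classical extended orthogonal Procrustes problem
with the closed-form SVD solution. For K' > K the coupling between rho and
A (|| Xc A ||^2 depends on A) removes the closed form; the classical
remedy is target augmentation: pad Y with K' - K *free* columns W, solve
the square problem X -> [Y, W] in closed form, refresh W with the mapped
extra coordinates, and repeat. Each sweep is monotone in the augmented
residual, so D (the residual on the real K target columns) converges; at
the fixed point the free columns absorb all source variance outside the
fitted subspace instead of shrinking rho. This matters: the naive
zero-padding solution contracts every projected point by the fraction of
source variance the target cannot represent, which is exactly the
shrinkage this placement method exists to avoid.

The similarity score t = sqrt(1 - D / tr(Yc^T Yc)) lies in [0, 1] and is
comparable across study individuals sharing one target configuration
because the denominator is the target's centered variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError

_MAX_SWEEPS = 5000
_REL_TOL = 1e-14
_N_STARTS = 8  # zero start + seeded random restarts; see fit docstring
_EARLY_EXIT_REL = 1e-9


@dataclass
class ProcrustesFit:
    """The fitted projection transform and its goodness-of-fit."""

    A: np.ndarray  # K'xK, orthonormal columns
    rho: float
    b: np.ndarray  # length K
    D: float  # minimized sum of squared distances
    t: float  # Procrustes similarity in [0, 1]
    x_mean: np.ndarray  # length K'
    y_mean: np.ndarray  # length K
    n_sweeps: int = 1


def _augmentation_sweeps(Xc, Yc, W, tr_x, tr_y, max_sweeps, rel_tol):
    """Run the alternating augmented-target iteration from one W start."""
    k = Yc.shape[1]
    D_prev = np.inf
    T = rho = s = None
    D = tr_y
    for sweep in range(1, max_sweeps + 1):
        C = Xc.T @ np.hstack([Yc, W])  # K'xK'
        U, s, Vt = np.linalg.svd(C)
        T = U @ Vt
        rho = float(s.sum()) / tr_x
        mapped = rho * (Xc @ T)
        W = mapped[:, k:]
        resid = mapped[:, :k] - Yc
        D = float(np.sum(resid * resid))
        if D_prev - D <= rel_tol * tr_y:
            break
        D_prev = D
    return min(D, D_prev), T, rho, s, sweep


def fit_projection_procrustes(
    X: np.ndarray,
    Y: np.ndarray,
    max_sweeps: int = _MAX_SWEEPS,
    rel_tol: float = _REL_TOL,
    n_starts: int = _N_STARTS,
) -> ProcrustesFit:
    """Solve the projection Procrustes problem.

    The augmentation iteration is run from a zero-padded start and, because
    the objective is non-convex in A for K' > K (roughly 1% of random
    instances have spurious fixed points), from ``n_starts - 1`` additional
    deterministic pseudo-random starts; the best D wins. Restarts stop
    early once D is negligible relative to the target variance, since no
    alternative optimum could improve a near-perfect fit meaningfully.

    Raises :class:`DegenerateInputError` when the centered source has rank
    below K or the target has zero variance. Near-degenerate singular
    values at the solution make A non-unique (D is still the optimum); a
    warning is emitted in that case.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError(f"incompatible shapes {X.shape} vs {Y.shape}")
    n, k_prime = X.shape
    k = Y.shape[1]
    if not (n >= k_prime >= k >= 1):
        raise ValueError(f"need N >= K' >= K >= 1, got N={n}, K'={k_prime}, K={k}")
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("non-finite coordinates")

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean

    tr_x = float(np.sum(Xc * Xc))
    tr_y = float(np.sum(Yc * Yc))
    if tr_y <= 0.0:
        raise DegenerateInputError("target configuration has zero variance")
    if np.linalg.matrix_rank(Xc) < k:
        raise DegenerateInputError("source configuration degenerate (rank < K)")

    C = Xc.T @ Yc
    S = Xc.T @ Xc

    def profile(A: np.ndarray):
        """Optimal rho and D for a fixed orthonormal-column A (sign-fixed so
        rho > 0): rho = tr(A^T C)/tr(A^T S A), D = trY - tr(A^T C)^2 / tr(A^T S A)."""
        num = float(np.sum(A * C))
        if num < 0:
            A = -A
            num = -num
        den = float(np.einsum("ij,ik,kj->", A, S, A))
        if den <= 0 or num == 0:
            return A, 0.0, tr_y
        return A, num / den, tr_y - num**2 / den

    # Square problem X -> [Yc | W]; W is the free padding refreshed with the
    # mapped extra coordinates each sweep (a no-op when K' == K).
    start_rng = np.random.default_rng(12345)  # fixed: restarts are deterministic
    best = None
    s_last = None
    total_sweeps = 0
    for start in range(max(1, n_starts)):
        if start == 0:
            W0 = np.zeros((n, k_prime - k))
        else:
            Q = np.linalg.qr(start_rng.standard_normal((k_prime, k_prime))).Q
            W0 = Xc @ Q[:, k:]
        _, T, _, s_last, sweeps = _augmentation_sweeps(
            Xc, Yc, W0, tr_x, tr_y, max_sweeps, rel_tol
        )
        total_sweeps += sweeps
        cand = profile(T[:, :k])
        if best is None or cand[2] < best[2]:
            best = cand
        if best[2] <= _EARLY_EXIT_REL * tr_y or k_prime == k:
            break

    if k == 1:
        # Exact for a one-column projection: the profiled objective
        # (u^T c)^2 / (u^T S u) is scale-invariant, so the unit-norm optimum
        # is the generalized eigenvector u ~ S^{-1} c.
        u, *_ = np.linalg.lstsq(S, C, rcond=None)
        norm = float(np.linalg.norm(u))
        if norm > 0:
            cand = profile(u / norm)
            if cand[2] < best[2]:
                best = cand

    A, rho, D = best
    if s_last[0] > 0 and (
        s_last[-1] < 1e-12 * s_last[0] or np.any(np.abs(np.diff(s_last)) < 1e-10 * s_last[0])
    ):
        warnings.warn(
            "near-degenerate singular values at the Procrustes solution: "
            "the projection A is not unique (D is unaffected)",
            RuntimeWarning,
        )

    D = max(0.0, D)
    t = procrustes_similarity(D, Y)
    b = y_mean - rho * (A.T @ x_mean)
    return ProcrustesFit(
        A=A, rho=rho, b=b, D=D, t=t, x_mean=x_mean, y_mean=y_mean, n_sweeps=total_sweeps
    )


def procrustes_similarity(D: float, Y: np.ndarray) -> float:
    """Similarity t = sqrt(max(0, 1 - D / tr(Yc^T Yc))), clamped into [0, 1]."""
    if D < 0:
        raise ValueError("D must be non-negative")
    Y = np.asarray(Y, dtype=np.float64)
    Yc = Y - Y.mean(axis=0)
    tr_y = float(np.sum(Yc * Yc))
    if tr_y <= 0.0:
        raise DegenerateInputError("target configuration has zero variance")
    return float(np.sqrt(max(0.0, 1.0 - D / tr_y)))


def apply_transform(fit: ProcrustesFit, x: np.ndarray) -> np.ndarray:
    """Map a point (or rows of points) from the source frame into the target
    frame: rho * (x - x_mean) A + y_mean. Affine in x."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != fit.A.shape[0]:
        raise ValueError(f"point has dimension {x.shape[-1]}, transform expects {fit.A.shape[0]}")
    return fit.rho * (x - fit.x_mean) @ fit.A + fit.y_mean
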