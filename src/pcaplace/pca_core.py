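"""PCA of the reference panel (the ancestry space S) and the per-sample
joint PCA of the N reference individuals plus one study individual (S').

The ancestry space is built once: the panel's dosage matrix is standardized
(column-mean imputation of missing cells, mean-centering, optional scaling
by sqrt(p(1-p)) with p the alt-allele frequency) and decomposed by SVD.
Reference coordinates are the top-K principal-component scores. Every study
sample later triggers its own joint PCA on the shared sites; the joint
frame S' differs from S, and the Procrustes step maps between them.

PC signs are arbitrary in any PCA; here each component's sign is fixed so
that the loading entry of largest absolute value is positive (ties broken
by lowest site index), which makes results reproducible across runs and
sample orderings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError
from .io_formats import ReferencePanel, SiteTable

CENTER_ONLY = "center_only"
CENTER_SCALE = "center_scale"
SCALING_MODES = (CENTER_ONLY, CENTER_SCALE)


@dataclass
class AncestrySpace:
    """The fixed K-dimensional reference coordinate system S.

    ``Y`` holds the reference individuals' coordinates; the standardization
    statistics (``site_means``, ``site_scales``) define how raw dosages map
    into the space and are persisted with it.
    """

    Y: np.ndarray  # N×K reference scores
    K: int
    eigenvalues: np.ndarray  # K, descending
    site_means: np.ndarray  # L
    site_scales: np.ndarray  # L
    scaling_mode: str
    sites: SiteTable

    def __post_init__(self) -> None:
        if self.Y.shape[1] != self.K:
            raise ValueError("Y column count does not match K")
        if not np.all(np.diff(self.eigenvalues) <= 1e-12 * max(1.0, self.eigenvalues[0])):
            raise ValueError("eigenvalues must be sorted descending")
        if self.scaling_mode not in SCALING_MODES:
            raise ValueError(f"unknown scaling mode {self.scaling_mode!r}")

    @property
    def n_reference(self) -> int:
        return self.Y.shape[0]


@dataclass
class JointPCAResult:
    """Scores of the N reference individuals plus one study individual in S'."""

    X_ref: np.ndarray  # N×K'
    x_study: np.ndarray  # K'
    K_prime: int


def standardize(
    G: np.ndarray,
    mode: str = CENTER_ONLY,
    means: np.ndarray | None = None,
    scales: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Impute, center and optionally scale a dosage matrix.

    Missing cells (nan) are imputed with the column mean. With
    ``mode='center_scale'`` columns are divided by sqrt(p(1-p)) where
    p = column_mean / 2; zero-variance columns get scale 1 so they
    contribute nothing rather than blowing up. When ``means``/``scales``
    are supplied (study-side standardization into an existing space) they
    are used instead of being recomputed.

    Returns ``(X, means, scales)``.
    """
    if mode not in SCALING_MODES:
        raise ValueError(f"unknown scaling mode {mode!r}")
    G = np.asarray(G, dtype=np.float64)
    if means is None:
        import warnings as _warnings

        with np.errstate(invalid="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # all-nan columns handled below
            means = np.nanmean(G, axis=0)
        if np.isnan(means).any():
            j = int(np.argmax(np.isnan(means)))
            raise DegenerateInputError(
                f"column {j} is entirely missing and no mean was supplied"
            )
    means = np.asarray(means, dtype=np.float64)

    if scales is None:
        if mode == CENTER_SCALE:
            p = means / 2.0
            var = p * (1.0 - p)
            scales = np.where(var > 0, np.sqrt(np.maximum(var, 0.0)), 1.0)
        else:
            scales = np.ones_like(means)
    scales = np.asarray(scales, dtype=np.float64)

    X = G.copy()
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.broadcast_to(means, X.shape)[nan_mask]
    X -= means
    X /= scales
    return X, means, scales


def _fix_signs(scores: np.ndarray, loadings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sign convention: the loading entry of largest absolute
    value is positive per component; ties resolve to the lowest site index
    (np.argmax takes the first maximum)."""
    flip = np.ones(loadings.shape[1])
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            flip[j] = -1.0
    return scores * flip, loadings * flip


def pca_reference(panel: ReferencePanel, K: int, mode: str = CENTER_ONLY) -> AncestrySpace:
    """Build the ancestry space S by PCA of the reference panel.

    Scores are left singular vectors scaled by singular values; eigenvalues
    are squared singular values over N-1.
    """
    n, l = panel.genotypes.shape
    if not 1 <= K <= min(n - 1, l):
        raise ValueError(f"K={K} must be in [1, min(N-1, L)] = [1, {min(n - 1, l)}]")
    X, means, scales = standardize(panel.genotypes, mode=mode)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :K] * s[:K]
    scores, _ = _fix_signs(scores, Vt[:K].T)
    eigenvalues = s[:K] ** 2 / (n - 1)
    return AncestrySpace(
        Y=scores, K=K, eigenvalues=eigenvalues,
        site_means=means, site_scales=scales,
        scaling_mode=mode, sites=panel.sites,
    )


def pca_joint(
    panel_rows: np.ndarray,
    study_row: np.ndarray,
    K_prime: int,
    mode: str = CENTER_ONLY,
) -> JointPCAResult:
    """Joint PCA of the N reference rows plus one study row on shared sites.

    Standardization statistics come from all N+1 rows together; the frame
    difference this introduces relative to S is absorbed downstream by the
    Procrustes fit. Accepts real-valued dosages (sequence mode) as well as
    hard genotypes.
    """
    study_row = np.asarray(study_row, dtype=np.float64)
    if np.isnan(study_row).all():
        raise DegenerateInputError("study dosage vector is entirely missing")
    n, l = panel_rows.shape
    if not 1 <= K_prime <= min(n, l):
        raise ValueError(f"K'={K_prime} must be in [1, min(N, L')] = [1, {min(n, l)}]")
    stacked = np.vstack([panel_rows, study_row[None, :]])
    X, _, _ = standardize(stacked, mode=mode)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :K_prime] * s[:K_prime]
    scores, _ = _fix_signs(scores, Vt[:K_prime].T)
    return JointPCAResult(X_ref=scores[:n], x_study=scores[n], K_prime=K_prime)


# ---------------------------------------------------------------------------
# persistence, so reference coordinates can be pre-computed once
# ---------------------------------------------------------------------------


def save_space(space: AncestrySpace, prefix: str | Path, sample_ids=None) -> None:
    """Persist to ``<prefix>.space.tsv`` (coordinates) and
    ``<prefix>.space.meta.tsv`` (standardization statistics + eigenvalues)."""
    prefix = str(prefix)
    ids = sample_ids if sample_ids is not None else np.arange(space.n_reference)
    coords = pd.DataFrame(space.Y, columns=[f"PC{i + 1}" for i in range(space.K)])
    coords.insert(0, "sample_id", ids)
    coords.to_csv(prefix + ".space.tsv", sep="\t", index=False, float_format="%.12g")

    meta = space.sites.df.copy()
    meta["site_mean"] = space.site_means
    meta["site_scale"] = space.site_scales
    eig = np.full(len(meta), np.nan)
    eig[: space.K] = space.eigenvalues
    meta["eigenvalue"] = eig
    meta.attrs["scaling_mode"] = space.scaling_mode
    with open(prefix + ".space.meta.tsv", "w") as fh:
        fh.write(f"# scaling_mode={space.scaling_mode}\n")
        meta.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def load_space(prefix: str | Path) -> tuple[AncestrySpace, np.ndarray]:
    """Load a persisted space; returns (space, reference sample_ids)."""
    prefix = str(prefix)
    coords = pd.read_csv(prefix + ".space.tsv", sep="\t")
    pc_cols = [c for c in coords.columns if c.startswith("PC")]
    with open(prefix + ".space.meta.tsv") as fh:
        first = fh.readline().strip()
        scaling_mode = first.split("scaling_mode=")[1] if "scaling_mode=" in first else CENTER_ONLY
        meta = pd.read_csv(fh, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    sites = SiteTable(
        meta[["site_id", "chrom", "pos", "ref", "alt"]]
        .astype({"site_id": str, "pos": np.int64})
        .reset_index(drop=True)
    )
    k = len(pc_cols)
    space = AncestrySpace(
        Y=coords[pc_cols].to_numpy(dtype=np.float64),
        K=k,
        eigenvalues=meta["eigenvalue"].to_numpy(dtype=np.float64)[:k],
        site_means=meta["site_mean"].to_numpy(dtype=np.float64),
        site_scales=meta["site_scale"].to_numpy(dtype=np.float64),
        scaling_mode=scaling_mode,
        sites=sites,
    )
    return space, coords["sample_id"].to_numpy(dtype=object)
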