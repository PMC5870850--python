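"""Post-placement quality diagnostics.

Two questions matter after a sample is placed. First, *where* did it land —
summarized by the ancestry composition of its k nearest reference
neighbors. Second, *should it have been placed at all* — a sample whose
ancestry is not represented in the panel will still land somewhere (PCA
placement has no "none of the above"), typically amid populations of a
distant genetic background. The Z score flags this: it compares the study
individual's genetic-variance statistic v with the same statistic computed
for its nearest reference neighbors on the same sites. In-panel individuals
match their neighbors (Z near 0); individuals from an unrepresented
population carry excess variance relative to the panel frequencies at
their landing spot and push |Z| up.

The variance statistic used here is the frequency-standardized mean squared
dosage deviation, v = mean_l (g_l - 2 p_l)^2 / (2 p_l (1 - p_l)), with p_l
the panel alt-allele frequency. Under Hardy-Weinberg draws from the panel
frequencies E[v] = 1. It is isolated behind
:func:`genetic_variance_statistic` so an alternative definition is a
one-function swap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError
from .io_formats import ReferencePanel
from .pca_core import AncestrySpace

FREQ_CLIP = (0.01, 0.99)  # keeps monomorphic-in-panel sites from exploding


@dataclass
class NeighborSet:
    indices: np.ndarray  # k reference-row indices, ascending distance
    distances: np.ndarray
    k: int

    def __post_init__(self) -> None:
        if len(self.indices) != self.k or len(self.distances) != self.k:
            raise ValueError("neighbor arrays do not match k")
        if self.k > 1 and (np.diff(self.distances) < -1e-12).any():
            raise ValueError("distances must be non-decreasing")
        if len(set(self.indices.tolist())) != self.k:
            raise ValueError("neighbor indices must be distinct")


@dataclass
class ZResult:
    Z: float
    v_study: float
    v_neighbors_mean: float
    v_neighbors_sd: float
    flagged: bool


def nearest_neighbors(space: AncestrySpace, coords: np.ndarray, k: int) -> NeighborSet:
    """The k reference individuals closest to ``coords`` in S (Euclidean);
    ties broken by lower reference index."""
    n = space.n_reference
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    d = np.linalg.norm(space.Y - np.asarray(coords, dtype=np.float64)[None, :], axis=1)
    order = np.argsort(d, kind="stable")[:k]
    return NeighborSet(indices=order, distances=d[order], k=k)


def knn_composition(neighbors: NeighborSet, populations: np.ndarray) -> dict[str, float]:
    """Population fractions among the k nearest neighbors; sums to 1."""
    labels, counts = np.unique(
        np.asarray(populations, dtype=object)[neighbors.indices], return_counts=True
    )
    return {str(lab): int(c) / neighbors.k for lab, c in zip(labels, counts)}


def genetic_variance_statistic(dosages: np.ndarray, ref_freqs: np.ndarray) -> float:
    """Frequency-standardized mean squared dosage deviation v (E[v] = 1
    in-panel under Hardy-Weinberg). Missing dosages are ignored; an
    all-missing vector is an error."""
    g = np.asarray(dosages, dtype=np.float64)
    p = np.clip(np.asarray(ref_freqs, dtype=np.float64), *FREQ_CLIP)
    observed = ~np.isnan(g)
    if not observed.any():
        raise DegenerateInputError("no observed dosages to compute genetic variance from")
    g, p = g[observed], p[observed]
    return float(np.mean((g - 2.0 * p) ** 2 / (2.0 * p * (1.0 - p))))


def z_score(
    v_study: float,
    space: AncestrySpace,
    panel: ReferencePanel,
    neighbors: NeighborSet,
    site_index: np.ndarray,
    threshold: float = 3.0,
) -> ZResult:
    """Standardize v_study against the neighbors' v distribution on the same
    site set. Needs k >= 5 for a usable spread estimate."""
    if neighbors.k < 5:
        raise ValueError(f"Z score needs at least 5 neighbors, got k={neighbors.k}")
    freqs = panel.allele_freqs()[site_index]
    v_nb = np.array(
        [
            genetic_variance_statistic(panel.genotypes[i, site_index], freqs)
            for i in neighbors.indices
        ]
    )
    mean = float(v_nb.mean())
    sd = float(v_nb.std(ddof=1))
    if sd == 0.0:
        warnings.warn("neighbor variance statistics are constant; Z set to 0", RuntimeWarning)
        z = 0.0
    else:
        z = (v_study - mean) / sd
    return ZResult(
        Z=float(z), v_study=float(v_study), v_neighbors_mean=mean,
        v_neighbors_sd=sd, flagged=bool(abs(z) > threshold),
    )
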