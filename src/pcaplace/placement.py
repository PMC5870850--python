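"""Per-study-individual placement pipeline.

Each study individual is handled independently: intersect its usable sites
with the panel, run a joint PCA of the N reference individuals plus this
one individual on those sites, fit the projection Procrustes map from the
joint frame onto the fixed reference coordinates Y, and push the study
point through the fitted map. Recomputing the joint PCA per sample is the
price of avoiding the shrinkage that fixed-loading projection suffers.

Genotype mode is deterministic. Sequence mode matches the study sample's
noise structure on the reference side: reads are simulated for every
reference individual at the study sample's own per-site depths and error
rates, so reference and study points live on the same noisy scale before
the joint PCA. With ``reps > 1`` the stochastic placement is repeated and
coordinates / t are averaged (t_sd reports the spread).

Reproducibility: one master seed; each sample gets an independent stream
seeded by a stable hash of (master seed, sample_id), so results do not
depend on sample order or worker count.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np

from .diagnostics import knn_composition, nearest_neighbors, genetic_variance_statistic, z_score
from .exceptions import DegenerateInputError, InsufficientSitesError, PcaplaceError
from .io_formats import PileupMatrix, ReferencePanel, StudyGenotypes
from .pca_core import CENTER_ONLY, AncestrySpace, pca_joint

logger = logging.getLogger(__name__)

GENOTYPE_MODE = "genotype"
SEQUENCE_MODE = "sequence"


@dataclass
class PlacementConfig:
    """Operating point of the placement pipeline.

    Defaults follow the worldwide-analysis convention K=4, K'=20; K' >= K is
    a method requirement. ``min_loci`` guards against placements from too
    few shared sites (t degrades and becomes meaningless below ~100 sites).
    """

    K: int = 4
    K_prime: int = 20
    mode: str = GENOTYPE_MODE
    reps: int = 1
    seed: int = 1
    min_loci: int = 100
    scaling_mode: str = CENTER_ONLY
    knn_k: int = 20
    z_threshold: float = 3.0

    def __post_init__(self) -> None:
        if self.K_prime < self.K:
            raise ValueError(f"K'={self.K_prime} must be >= K={self.K}")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.mode not in (GENOTYPE_MODE, SEQUENCE_MODE):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class Placement:
    """One study individual's coordinates in S plus quality diagnostics."""

    sample_id: str
    coords: np.ndarray  # length K
    t: float
    t_sd: float
    L_used: int
    Z: float | None = None
    knn: dict[str, float] | None = None
    reps: int = 1


@dataclass
class PlacementFailure:
    sample_id: str
    error: str


def _derive_seed(master: int, sample_id: str) -> int:
    """Stable per-sample seed below 2^31, independent of sample order."""
    digest = hashlib.sha256(f"{master}:{sample_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _effective_k_prime(cfg: PlacementConfig, n: int, l_used: int) -> int:
    cap = min(n, l_used)
    if cfg.K_prime > cap:
        logger.warning("K'=%d exceeds achievable rank %d; lowering", cfg.K_prime, cap)
        if cap < cfg.K:
            raise DegenerateInputError(
                f"achievable rank {cap} is below K={cfg.K}; cannot place"
            )
        return cap
    return cfg.K_prime


def _annotate(
    placement: Placement,
    study_dosages: np.ndarray,
    site_idx: np.ndarray,
    panel: ReferencePanel,
    space: AncestrySpace,
    cfg: PlacementConfig,
) -> Placement:
    """Fill the kNN composition and Z diagnostic on a fitted placement."""
    k = min(cfg.knn_k, panel.n_samples)
    neighbors = nearest_neighbors(space, placement.coords, k)
    placement.knn = knn_composition(neighbors, panel.population)
    if k >= 5:
        freqs = panel.allele_freqs()[site_idx]
        v_study = genetic_variance_statistic(study_dosages, freqs)
        zres = z_score(v_study, space, panel, neighbors, site_idx, threshold=cfg.z_threshold)
        placement.Z = zres.Z
    return placement


def place_genotype_sample(
    panel: ReferencePanel,
    space: AncestrySpace,
    study: StudyGenotypes,
    sample_index: int,
    cfg: PlacementConfig,
) -> Placement:
    """Place one genotyped study individual. Deterministic."""
    g = study.genotypes[sample_index]
    observed = ~np.isnan(g)
    site_idx = study.site_index[observed]
    l_used = int(site_idx.size)
    if l_used < cfg.min_loci:
        raise InsufficientSitesError(
            f"sample {study.sample_ids[sample_index]!r}: {l_used} usable sites "
            f"shared with the panel, need at least {cfg.min_loci}"
        )
    if l_used < 1000:
        logger.warning(
            "sample %s: only %d shared sites; placement may be unstable",
            study.sample_ids[sample_index], l_used,
        )
    k_prime = _effective_k_prime(cfg, panel.n_samples, l_used)
    joint = pca_joint(panel.genotypes[:, site_idx], g[observed], k_prime, cfg.scaling_mode)

    from .procrustes import apply_transform, fit_projection_procrustes

    fit = fit_projection_procrustes(joint.X_ref, space.Y)
    coords = apply_transform(fit, joint.x_study)
    placement = Placement(
        sample_id=str(study.sample_ids[sample_index]),
        coords=coords, t=fit.t, t_sd=0.0, L_used=l_used, reps=1,
    )
    return _annotate(placement, g[observed], site_idx, panel, space, cfg)


def simulate_reference_reads(
    panel_rows: np.ndarray,
    depth_profile: np.ndarray,
    error_rate: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate read-based dosages for the reference individuals at the study
    sample's own coverage.

    For genotype g at a site with c reads and base-error rate eps, the
    alt-read count is Binomial(c, p_g) with p_g = (g/2)(1-eps) + (1-g/2)eps;
    the returned dosage is 2*alt/c (missing where c = 0 or g is missing).
    """
    g = np.asarray(panel_rows, dtype=np.float64)
    c = np.asarray(depth_profile, dtype=np.int64)[None, :]
    eps = np.asarray(error_rate, dtype=np.float64)[None, :]
    p_alt = (g / 2.0) * (1.0 - eps) + (1.0 - g / 2.0) * eps
    valid = ~np.isnan(p_alt) & (np.broadcast_to(c, g.shape) > 0)
    p_draw = np.where(valid, p_alt, 0.0)
    alt = rng.binomial(np.broadcast_to(c, g.shape), p_draw)
    with np.errstate(divide="ignore", invalid="ignore"):
        dosage = 2.0 * alt / c
    dosage = np.where(valid, dosage, np.nan)
    return dosage


def place_sequence_sample(
    panel: ReferencePanel,
    space: AncestrySpace,
    pileup: PileupMatrix,
    sample_index: int,
    cfg: PlacementConfig,
    rng: np.random.Generator | None = None,
) -> Placement:
    """Place one sequenced study individual from read counts.

    The study dosage at a covered site is the observed alt-read fraction
    times two (2 - 2*ref_count/depth); no genotype calling or error
    correction is applied to it — the error rate enters only through the
    reference-read simulation, keeping both sides equally noisy.
    """
    sample_id = str(pileup.sample_ids[sample_index])
    depth = pileup.depth[sample_index]
    ref_count = pileup.ref_count[sample_index]
    covered = depth > 0
    site_idx = pileup.site_index[covered]
    l_used = int(site_idx.size)
    if l_used < cfg.min_loci:
        raise InsufficientSitesError(
            f"sample {sample_id!r}: {l_used} covered sites shared with the panel, "
            f"need at least {cfg.min_loci}"
        )
    study_dosage = 2.0 - 2.0 * ref_count[covered] / depth[covered]
    err = pileup.error_rate[covered]
    k_prime = _effective_k_prime(cfg, panel.n_samples, l_used)
    if rng is None:
        rng = np.random.default_rng(_derive_seed(cfg.seed, sample_id))

    from .procrustes import apply_transform, fit_projection_procrustes

    coords_reps = np.empty((cfg.reps, space.K))
    t_reps = np.empty(cfg.reps)
    for r in range(cfg.reps):
        ref_dosage = simulate_reference_reads(
            panel.genotypes[:, site_idx], depth[covered], err, rng
        )
        joint = pca_joint(ref_dosage, study_dosage, k_prime, cfg.scaling_mode)
        fit = fit_projection_procrustes(joint.X_ref, space.Y)
        coords_reps[r] = apply_transform(fit, joint.x_study)
        t_reps[r] = fit.t

    placement = Placement(
        sample_id=sample_id,
        coords=coords_reps.mean(axis=0),
        t=float(t_reps.mean()),
        t_sd=float(t_reps.std(ddof=0)) if cfg.reps > 1 else 0.0,
        L_used=l_used,
        reps=cfg.reps,
    )
    return _annotate(placement, study_dosage, site_idx, panel, space, cfg)


def place_all(
    panel: ReferencePanel,
    space: AncestrySpace,
    study_input: StudyGenotypes | PileupMatrix,
    cfg: PlacementConfig,
    workers: int = 1,
) -> tuple[list[Placement], list[PlacementFailure]]:
    """Place every study sample; failures are collected, never fatal.

    Output order follows the input sample order and is byte-stable in the
    worker count: each sample's randomness comes from its own (seed,
    sample_id)-derived stream.
    """
    if cfg.mode == SEQUENCE_MODE and not isinstance(study_input, PileupMatrix):
        raise PcaplaceError("sequence mode requires a PileupMatrix input")
    if cfg.mode == GENOTYPE_MODE and not isinstance(study_input, StudyGenotypes):
        raise PcaplaceError("genotype mode requires a StudyGenotypes input")

    def _one(i: int) -> Placement:
        if cfg.mode == GENOTYPE_MODE:
            return place_genotype_sample(panel, space, study_input, i, cfg)
        return place_sequence_sample(panel, space, study_input, i, cfg)

    indices = range(study_input.n_samples)
    if workers > 1:
        from concurrent.futures import ThreadPoolExecutor

        def _safe(i: int):
            try:
                return _one(i)
            except PcaplaceError as exc:
                return PlacementFailure(str(study_input.sample_ids[i]), str(exc))

        with ThreadPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(_safe, indices))
    else:
        results = []
        for i in indices:
            try:
                results.append(_one(i))
            except PcaplaceError as exc:
                results.append(PlacementFailure(str(study_input.sample_ids[i]), str(exc)))

    placements = [r for r in results if isinstance(r, Placement)]
    failures = [r for r in results if isinstance(r, PlacementFailure)]
    for f in failures:
        logger.warning("sample %s failed: %s", f.sample_id, f.error)
    return placements, failures
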