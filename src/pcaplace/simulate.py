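"""Synthetic multi-population cohorts and sequencing reads.

Population structure follows the Balding-Nichols model: each site has an
ancestral alt-allele frequency p drawn uniformly from a configured range,
and each population perturbs it with a Beta draw

    q_pop ~ Beta( p (1-F)/F , (1-p)(1-F)/F ),

whose variance around p is F p (1-p) — F plays the role of the population's
divergence (Fst) from the ancestral pool. Genotypes are Binomial(2, q)
draws; sites are unlinked. This is enough to produce the clustered PC
structure the placement method consumes; it deliberately omits LD,
admixture LD, selection and realistic demography.

Study individuals can be drawn from the panel populations, from per-
individual admixture proportions (genotypes ~ Binomial(2, sum_a alpha_a
q_a)), or from a freshly diverged outgroup absent from the panel (for
exercising the reference-appropriateness diagnostic). Sequencing reads are
Poisson coverage with symmetric base-miscall error.

Everything is deterministic in the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    PileupMatrix,
    ReferencePanel,
    SiteTable,
    StudyGenotypes,
    write_pileup,
    write_reference_panel,
    write_vcf_genotypes,
)

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Generator settings.

    Defaults emulate a small continental-scale panel: 3 populations of 50
    individuals at 2000 unlinked SNPs with pairwise divergence F=0.1,
    shallow 5x coverage and a 1% base-error rate for sequence data.
    """

    n_pops: int = 3
    n_per_pop: int | tuple[int, ...] = 50
    L: int = 2000
    Fst: float | tuple[float, ...] = 0.1
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    depth_mean: float = 5.0
    error_rate: float = 0.01
    seed: int = 0
    outgroup_Fst: float | None = None

    def __post_init__(self) -> None:
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("ancestral_freq_range must be inside (0, 1)")
        for f in np.atleast_1d(self.Fst):
            if not 0.0 < f < 1.0:
                raise ValueError("Fst must be in (0, 1)")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")

    @property
    def pop_sizes(self) -> np.ndarray:
        if np.isscalar(self.n_per_pop):
            return np.full(self.n_pops, int(self.n_per_pop))
        sizes = np.asarray(self.n_per_pop, dtype=int)
        if len(sizes) != self.n_pops:
            raise ValueError("n_per_pop length must equal n_pops")
        return sizes

    @property
    def pop_fst(self) -> np.ndarray:
        if np.isscalar(self.Fst):
            return np.full(self.n_pops, float(self.Fst))
        f = np.asarray(self.Fst, dtype=float)
        if len(f) != self.n_pops:
            raise ValueError("Fst length must equal n_pops")
        return f


@dataclass
class PanelTruth:
    """Ground truth behind a simulated panel, for test harnesses."""

    ancestral_freq: np.ndarray  # L
    pop_freqs: np.ndarray  # n_pops × L
    pop_names: list[str]


def _balding_nichols(ancestral: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    a = ancestral * (1.0 - F) / F
    b = (1.0 - ancestral) * (1.0 - F) / F
    return rng.beta(a, b)


def _make_sites(L: int, rng: np.random.Generator) -> SiteTable:
    pos = np.sort(rng.choice(np.arange(1, 50 * L + 1), size=L, replace=False))
    ref_idx = rng.integers(0, 4, size=L)
    alt_idx = (ref_idx + rng.integers(1, 4, size=L)) % 4
    df = pd.DataFrame(
        {
            "site_id": [f"snp{i + 1}" for i in range(L)],
            "chrom": "1",
            "pos": pos.astype(np.int64),
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
        }
    )
    return SiteTable(df)


def simulate_panel(cfg: SimConfig) -> tuple[ReferencePanel, PanelTruth]:
    """Generate a structured reference panel plus its true frequencies."""
    rng = np.random.default_rng(cfg.seed)
    sites = _make_sites(cfg.L, rng)
    lo, hi = cfg.ancestral_freq_range
    ancestral = rng.uniform(lo, hi, size=cfg.L)

    sizes = cfg.pop_sizes
    fsts = cfg.pop_fst
    pop_freqs = np.vstack(
        [_balding_nichols(ancestral, fsts[a], rng) for a in range(cfg.n_pops)]
    )
    genotypes = np.vstack(
        [
            rng.binomial(2, pop_freqs[a], size=(sizes[a], cfg.L)).astype(np.float64)
            for a in range(cfg.n_pops)
        ]
    )
    pop_names = [f"POP{a + 1}" for a in range(cfg.n_pops)]
    population = np.concatenate(
        [np.full(sizes[a], pop_names[a], dtype=object) for a in range(cfg.n_pops)]
    )
    sample_ids = np.array([f"ref{i + 1}" for i in range(int(sizes.sum()))], dtype=object)
    panel = ReferencePanel(
        genotypes=genotypes, sites=sites, sample_ids=sample_ids, population=population
    )
    return panel, PanelTruth(ancestral_freq=ancestral, pop_freqs=pop_freqs, pop_names=pop_names)


def simulate_study(
    truth: PanelTruth,
    cfg: SimConfig,
    assignments: list[int | str] | None = None,
    admixture: np.ndarray | None = None,
    seed: int | None = None,
    sample_prefix: str = "study",
) -> StudyGenotypes:
    """Draw study individuals at all panel sites.

    ``assignments`` holds one entry per individual: a population index or
    the string ``"outgroup"`` (requires ``cfg.outgroup_Fst``; one outgroup
    frequency vector is drawn and shared by all outgroup individuals).
    Alternatively ``admixture`` is an M × n_pops matrix of proportions
    (rows sum to 1) and genotypes come from the mixed frequencies.
    """
    if (assignments is None) == (admixture is None):
        raise ValueError("provide exactly one of assignments / admixture")
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)

    if admixture is not None:
        alpha = np.asarray(admixture, dtype=float)
        if alpha.ndim != 2 or alpha.shape[1] != truth.pop_freqs.shape[0]:
            raise ValueError("admixture must be M × n_pops")
        if not np.allclose(alpha.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("admixture proportions must sum to 1 per individual")
        freqs = alpha @ truth.pop_freqs  # M × L
    else:
        out_freq = None
        if any(a == "outgroup" for a in assignments):
            if cfg.outgroup_Fst is None:
                raise ValueError("outgroup individuals need cfg.outgroup_Fst")
            out_freq = _balding_nichols(truth.ancestral_freq, cfg.outgroup_Fst, rng)
        rows = []
        for a in assignments:
            rows.append(out_freq if a == "outgroup" else truth.pop_freqs[int(a)])
        freqs = np.vstack(rows)

    genotypes = rng.binomial(2, freqs).astype(np.float64)
    m = genotypes.shape[0]
    return StudyGenotypes(
        genotypes=genotypes,
        sample_ids=np.array([f"{sample_prefix}{i + 1}" for i in range(m)], dtype=object),
        site_index=np.arange(truth.pop_freqs.shape[1], dtype=np.int64),
    )


def simulate_reads(
    study: StudyGenotypes,
    cfg: SimConfig,
    seed: int | None = None,
    site_subset: np.ndarray | None = None,
) -> PileupMatrix:
    """Generate Poisson-coverage reads with symmetric base error for every
    study individual. ``site_subset`` (indices into the study's site axis)
    restricts coverage to a targeted set, emulating exome-style data."""
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    g = study.genotypes
    m, l = g.shape
    cols = np.arange(l) if site_subset is None else np.asarray(site_subset, dtype=np.int64)
    gs = g[:, cols]
    depth = rng.poisson(cfg.depth_mean, size=gs.shape)
    eps = cfg.error_rate
    p_ref = (1.0 - gs / 2.0) * (1.0 - eps) + (gs / 2.0) * eps
    missing = np.isnan(p_ref)
    depth[missing] = 0
    ref_count = rng.binomial(depth, np.where(missing, 0.0, p_ref))
    return PileupMatrix(
        depth=depth.astype(np.int64),
        ref_count=ref_count.astype(np.int64),
        error_rate=np.full(len(cols), float(eps)),
        sample_ids=study.sample_ids.copy(),
        site_index=study.site_index[cols],
    )


def write_fixture_set(
    out_dir: str | Path,
    cfg: SimConfig,
    n_study_per_pop: int = 5,
) -> dict[str, Path]:
    """Write a complete on-disk fixture: panel files, study VCF, pileup +
    error-rate files, and a truth table mapping study samples to their true
    population. Returns the paths keyed by role."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel, truth = simulate_panel(cfg)
    assignments: list[int | str] = [
        a for a in range(cfg.n_pops) for _ in range(n_study_per_pop)
    ]
    study = simulate_study(truth, cfg, assignments=assignments)
    pileup = simulate_reads(study, cfg)

    prefix = out_dir / "panel"
    write_reference_panel(panel, prefix)
    paths = {
        "geno": Path(str(prefix) + ".geno"),
        "site": Path(str(prefix) + ".site"),
        "sample": Path(str(prefix) + ".sample"),
        "vcf": out_dir / "study.vcf",
        "pileup": out_dir / "study.pileup",
        "siterr": out_dir / "study.siterr",
        "truth": out_dir / "study.truth.tsv",
    }
    write_vcf_genotypes(study, panel.sites, paths["vcf"])
    write_pileup(pileup, panel.sites, paths["pileup"], paths["siterr"])
    pd.DataFrame(
        {
            "sample_id": study.sample_ids,
            "true_population": [truth.pop_names[int(a)] for a in assignments],
        }
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths
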