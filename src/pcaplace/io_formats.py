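"""Readers and writers for every on-disk representation.

The reference panel lives in three tab/whitespace-separated files sharing a
prefix:

``<prefix>.geno``
    one row per sample, whitespace-separated integer alt-allele dosages in
    {0, 1, 2}, with ``-9`` marking a missing genotype;
``<prefix>.site``
    header ``site_id  chrom  pos  ref  alt`` followed by one row per site,
    positions 1-based, rows ordered by (chrom, pos);
``<prefix>.sample``
    header ``sample_id  population`` (optional third column ``region``)
    followed by one row per sample.

Study genotypes come from standard VCF (plain or bgzipped, GT required).
Sequence-mode input is a long-format pileup table (header
``sample_id  site_id  depth  ref_count``, one row per covered sample/site
cell) plus a per-site base-error file (header ``site_id  error_rate``).
Lines starting with ``#`` are comments in both; writers emit a dialect
version comment (``pcaplace-pileup-v1``).

Internally, genotypes and dosages are float64 matrices with ``nan`` for
missing; integer codes exist only on disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import FormatError

logger = logging.getLogger(__name__)

MISSING_CODE = -9
_BASES = frozenset("ACGT")

SITE_COLUMNS = ["site_id", "chrom", "pos", "ref", "alt"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteTable:
    """The panel's variant set: biallelic SNPs keyed by (chrom, pos).

    Wraps a DataFrame with columns ``site_id, chrom, pos, ref, alt``; rows
    are ordered by (chrom, pos) and (chrom, pos) is unique.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if list(df.columns) != SITE_COLUMNS:
            raise FormatError(f"site table columns must be {SITE_COLUMNS}, got {list(df.columns)}")
        if df["pos"].dtype.kind not in "iu":
            raise FormatError("site positions must be integers")
        bad = ~(df["ref"].isin(_BASES) & df["alt"].isin(_BASES))
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(f"non-ACGT allele at site row {i} ({df['site_id'].iloc[i]!r})")
        if (df["ref"] == df["alt"]).any():
            raise FormatError("ref allele equals alt allele at some site")
        keys = list(zip(df["chrom"], df["pos"]))
        if len(set(keys)) != len(keys):
            raise FormatError("duplicate (chrom, pos) in site table")
        if keys != sorted(keys, key=lambda t: (str(t[0]), int(t[1]))):
            raise FormatError("site table rows must be ordered by (chrom, pos)")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def site_ids(self) -> np.ndarray:
        return self.df["site_id"].to_numpy()

    def position_index(self) -> dict[tuple[str, int], int]:
        """Map (chrom, pos) -> row index."""
        return {
            (str(c), int(p)): i
            for i, (c, p) in enumerate(zip(self.df["chrom"], self.df["pos"]))
        }

    def id_index(self) -> dict[str, int]:
        return {str(s): i for i, s in enumerate(self.df["site_id"])}


@dataclass
class ReferencePanel:
    """N reference individuals × L sites of hard genotypes with population labels."""

    genotypes: np.ndarray  # N×L float64, values {0,1,2,nan}
    sites: SiteTable
    sample_ids: np.ndarray
    population: np.ndarray
    region: np.ndarray | None = None

    def __post_init__(self) -> None:
        n, l = self.genotypes.shape
        if len(self.sites) != l:
            raise FormatError(
                f"genotype matrix has {l} sites but site table has {len(self.sites)} rows"
            )
        if len(self.sample_ids) != n or len(self.population) != n:
            raise FormatError("sample/population labels do not match genotype row count")
        if any(not str(p) for p in self.population):
            raise FormatError("every sample needs a population label")
        g = self.genotypes
        ok = np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0))
        if not ok.all():
            raise FormatError("reference genotypes must be in {0,1,2} or missing")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def allele_freqs(self) -> np.ndarray:
        """Per-site alt-allele frequency from non-missing panel genotypes."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.genotypes, axis=0) / 2.0

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.genotypes).mean(axis=0)


@dataclass
class StudyGenotypes:
    """M study individuals' dosages aligned to a subset of the panel sites."""

    genotypes: np.ndarray  # M×L' float64 {0,1,2,nan}
    sample_ids: np.ndarray
    site_index: np.ndarray  # L' indices into the panel SiteTable, strictly increasing

    def __post_init__(self) -> None:
        m, l = self.genotypes.shape
        if len(self.sample_ids) != m:
            raise FormatError("sample_ids length does not match genotype rows")
        if len(self.site_index) != l:
            raise FormatError("site_index length does not match genotype columns")
        if l > 1 and not (np.diff(self.site_index) > 0).all():
            raise FormatError("site_index must be strictly increasing")
        g = self.genotypes
        ok = np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0))
        if not ok.all():
            raise FormatError("study genotypes must be in {0,1,2} or missing")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]


@dataclass
class PileupMatrix:
    """Per-sample, per-site read depth / reference-allele count / base-error rate."""

    depth: np.ndarray  # M×L' int
    ref_count: np.ndarray  # M×L' int
    error_rate: np.ndarray  # L' in [0, 0.5)
    sample_ids: np.ndarray
    site_index: np.ndarray

    def __post_init__(self) -> None:
        if self.depth.shape != self.ref_count.shape:
            raise FormatError("depth and ref_count shapes differ")
        if (self.ref_count > self.depth).any():
            i, j = np.argwhere(self.ref_count > self.depth)[0]
            raise FormatError(
                f"ref_count exceeds depth for sample {self.sample_ids[i]!r} "
                f"at site column {j}"
            )
        if (self.depth < 0).any():
            raise FormatError("negative read depth")
        e = self.error_rate
        if not (np.isfinite(e).all() and (e >= 0).all() and (e < 0.5).all()):
            raise FormatError("error rates must be finite and in [0, 0.5)")
        if len(e) != self.depth.shape[1] or len(self.site_index) != self.depth.shape[1]:
            raise FormatError("error_rate/site_index length does not match site columns")
        if len(self.sample_ids) != self.depth.shape[0]:
            raise FormatError("sample_ids length does not match depth rows")

    @property
    def n_samples(self) -> int:
        return self.depth.shape[0]


# ---------------------------------------------------------------------------
# reference panel files
# ---------------------------------------------------------------------------


def read_site_table(site_path: str | Path) -> SiteTable:
    df = pd.read_csv(site_path, sep="\t", comment="#", dtype={"chrom": str, "ref": str, "alt": str})
    missing_cols = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{site_path}: missing columns {missing_cols}")
    df = df[SITE_COLUMNS].copy()
    df["site_id"] = df["site_id"].astype(str)
    df["pos"] = df["pos"].astype(np.int64)
    return SiteTable(df.reset_index(drop=True))


def read_reference_panel(
    geno_path: str | Path,
    site_path: str | Path,
    sample_path: str | Path,
    max_missing: float = 0.5,
) -> ReferencePanel:
    """Load and cross-validate the three-file reference panel.

    ``max_missing`` is the per-site missing-fraction ceiling; sites above it
    make the panel invalid (the panel is the anchor dataset, so it is
    rejected rather than silently filtered).
    """
    sites = read_site_table(site_path)

    samples = pd.read_csv(sample_path, sep="\t", comment="#", dtype=str)
    if "sample_id" not in samples.columns or "population" not in samples.columns:
        raise FormatError(f"{sample_path}: needs sample_id and population columns")

    try:
        geno = np.loadtxt(geno_path, dtype=np.float64, comments="#", ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{geno_path}: {exc}") from exc
    if geno.shape[0] != len(samples):
        raise FormatError(
            f"{geno_path}: {geno.shape[0]} genotype rows but "
            f"{sample_path} lists {len(samples)} samples"
        )
    if geno.shape[1] != len(sites):
        raise FormatError(
            f"{geno_path}: {geno.shape[1]} genotype columns but "
            f"{site_path} lists {len(sites)} sites"
        )
    geno[geno == MISSING_CODE] = np.nan

    panel = ReferencePanel(
        genotypes=geno,
        sites=sites,
        sample_ids=samples["sample_id"].to_numpy(dtype=object),
        population=samples["population"].to_numpy(dtype=object),
        region=samples["region"].to_numpy(dtype=object) if "region" in samples.columns else None,
    )
    frac = panel.missing_fraction()
    if (frac > max_missing).any():
        j = int(np.argmax(frac))
        raise FormatError(
            f"{geno_path}: site {panel.sites.site_ids[j]!r} has missing fraction "
            f"{frac[j]:.2f} > ceiling {max_missing}"
        )
    return panel


def write_reference_panel(panel: ReferencePanel, prefix: str | Path) -> None:
    """Write ``<prefix>.geno/.site/.sample``."""
    prefix = str(prefix)
    geno = panel.genotypes.copy()
    geno[np.isnan(geno)] = MISSING_CODE
    np.savetxt(prefix + ".geno", geno.astype(np.int64), fmt="%d", delimiter=" ")
    panel.sites.df.to_csv(prefix + ".site", sep="\t", index=False)
    cols = {"sample_id": panel.sample_ids, "population": panel.population}
    if panel.region is not None:
        cols["region"] = panel.region
    pd.DataFrame(cols).to_csv(prefix + ".sample", sep="\t", index=False)


def read_reference_panel_prefix(prefix: str | Path, max_missing: float = 0.5) -> ReferencePanel:
    prefix = str(prefix)
    return read_reference_panel(
        prefix + ".geno", prefix + ".site", prefix + ".sample", max_missing=max_missing
    )


# ---------------------------------------------------------------------------
# VCF study genotypes
# ---------------------------------------------------------------------------


def read_vcf_genotypes(
    vcf_path: str | Path,
    sites: SiteTable,
    allele_policy: str = "swap",
) -> StudyGenotypes:
    """Read study genotypes from VCF, intersected with the panel sites.

    Records are matched to panel sites by (chrom, pos). If the record's
    (REF, ALT) equals the panel's (ref, alt) the dosage is the alt-allele
    count; if the alleles are swapped the dosage is ``2 - count`` (unless
    ``allele_policy='exact'``). Any other allele pair, multi-allelic records,
    and non-SNP alleles are dropped. Strand flips are never attempted.
    Missing GT becomes ``nan``.
    """
    from cyvcf2 import VCF

    if allele_policy not in ("swap", "exact"):
        raise ValueError(f"unknown allele_policy {allele_policy!r}")

    pos_index = sites.position_index()
    refs = sites.df["ref"].to_numpy()
    alts = sites.df["alt"].to_numpy()

    vcf = VCF(str(vcf_path))
    sample_ids = np.asarray(vcf.samples, dtype=object)
    m = len(sample_ids)

    dosages: dict[int, np.ndarray] = {}
    n_dropped_alleles = 0
    for var in vcf:
        key = (str(var.CHROM), int(var.POS))
        j = pos_index.get(key)
        if j is None:
            continue
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_dropped_alleles += 1
            continue
        ref, alt = var.REF.upper(), var.ALT[0].upper()
        if (ref, alt) == (refs[j], alts[j]):
            flip = False
        elif allele_policy == "swap" and (alt, ref) == (refs[j], alts[j]):
            flip = True
        else:
            n_dropped_alleles += 1
            continue
        row = np.full(m, np.nan)
        for i, gt in enumerate(var.genotypes):
            a = gt[:-1]  # last element is the phase flag
            if len(a) != 2 or a[0] < 0 or a[1] < 0:
                continue
            row[i] = float(int(a[0] == 1) + int(a[1] == 1))
        if flip:
            row = 2.0 - row
        dosages[j] = row
    vcf.close()

    if not dosages:
        raise FormatError(
            f"{vcf_path}: no sites overlap the reference panel; "
            "check chromosome naming and consider a different panel"
        )
    if n_dropped_alleles:
        logger.info("%s: dropped %d records with irreconcilable alleles", vcf_path, n_dropped_alleles)

    site_index = np.array(sorted(dosages), dtype=np.int64)
    geno = np.column_stack([dosages[j] for j in site_index])
    return StudyGenotypes(genotypes=geno, sample_ids=sample_ids, site_index=site_index)


def write_vcf_genotypes(
    study: StudyGenotypes,
    sites: SiteTable,
    path: str | Path,
) -> None:
    """Write study genotypes as a minimal VCFv4.2 text file (GT only)."""
    df = sites.df.iloc[study.site_index]
    gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(df["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in study.sample_ids)
            + "\n"
        )
        for col, (_, row) in enumerate(df.iterrows()):
            calls = [
                gt_codes.get(g, "./.") if not np.isnan(g) else "./."
                for g in study.genotypes[:, col]
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['site_id']}\t{row['ref']}\t{row['alt']}"
                f"\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# pileup matrices
# ---------------------------------------------------------------------------


def read_pileup(
    pileup_path: str | Path,
    siterr_path: str | Path,
    sites: SiteTable,
) -> PileupMatrix:
    """Read a long-format pileup table plus its per-site error-rate file.

    Sites absent from the panel are dropped (with a logged count); the
    returned matrix covers the union of covered panel sites across samples,
    zero depth meaning "not covered for this sample".
    """
    df = pd.read_csv(
        pileup_path, sep="\t", comment="#",
        dtype={"sample_id": str, "site_id": str},
    )
    for col in ("sample_id", "site_id", "depth", "ref_count"):
        if col not in df.columns:
            raise FormatError(f"{pileup_path}: missing column {col!r}")
    err = pd.read_csv(siterr_path, sep="\t", comment="#", dtype={"site_id": str})
    if "site_id" not in err.columns or "error_rate" not in err.columns:
        raise FormatError(f"{siterr_path}: needs site_id and error_rate columns")
    err_map: Mapping[str, float] = dict(zip(err["site_id"], err["error_rate"].astype(float)))

    id_index = sites.id_index()
    known = df["site_id"].map(id_index)
    n_dropped = int(known.isna().sum())
    if n_dropped:
        logger.info("%s: dropped %d rows at sites absent from the panel", pileup_path, n_dropped)
        df = df[known.notna()]
        known = known[known.notna()]

    bad = df["ref_count"].astype(int) > df["depth"].astype(int)
    if bad.any():
        r = df[bad].iloc[0]
        raise FormatError(
            f"{pileup_path}: ref_count {r['ref_count']} > depth {r['depth']} "
            f"for sample {r['sample_id']!r} at site {r['site_id']!r}"
        )

    sample_ids = np.asarray(pd.unique(df["sample_id"]), dtype=object)
    site_index = np.array(sorted(set(known.astype(int))), dtype=np.int64)
    col_of = {int(j): c for c, j in enumerate(site_index)}
    row_of = {s: r for r, s in enumerate(sample_ids)}

    m, l = len(sample_ids), len(site_index)
    depth = np.zeros((m, l), dtype=np.int64)
    ref_count = np.zeros((m, l), dtype=np.int64)
    for s, j, d, rc in zip(df["sample_id"], known.astype(int), df["depth"], df["ref_count"]):
        depth[row_of[s], col_of[j]] = int(d)
        ref_count[row_of[s], col_of[j]] = int(rc)

    missing_err = [
        sid for sid in sites.site_ids[site_index] if sid not in err_map
    ]
    if missing_err:
        raise FormatError(f"{siterr_path}: no error rate for site {missing_err[0]!r}")
    error_rate = np.array([err_map[s] for s in sites.site_ids[site_index]], dtype=float)

    return PileupMatrix(
        depth=depth, ref_count=ref_count, error_rate=error_rate,
        sample_ids=sample_ids, site_index=site_index,
    )


def write_pileup(
    pileup: PileupMatrix,
    sites: SiteTable,
    pileup_path: str | Path,
    siterr_path: str | Path,
) -> None:
    site_ids = sites.site_ids[pileup.site_index]
    with open(pileup_path, "w") as fh:
        fh.write("# pcaplace-pileup-v1\n")
        fh.write("sample_id\tsite_id\tdepth\tref_count\n")
        for i, sid in enumerate(pileup.sample_ids):
            covered = np.flatnonzero(pileup.depth[i] > 0)
            for j in covered:
                fh.write(f"{sid}\t{site_ids[j]}\t{pileup.depth[i, j]}\t{pileup.ref_count[i, j]}\n")
    with open(siterr_path, "w") as fh:
        fh.write("# pcaplace-siterr-v1\n")
        fh.write("site_id\terror_rate\n")
        for sid, e in zip(site_ids, pileup.error_rate):
            fh.write(f"{sid}\t{e:.10g}\n")


# ---------------------------------------------------------------------------
# placement output
# ---------------------------------------------------------------------------


def write_placements(placements: Iterable, path: str | Path) -> None:
    """Write the tab-separated placement table.

    Columns: ``sample_id  L_used  t  Z  PC1..PCK  knn_top_population
    knn_top_fraction``; floats at 12 significant digits so a round-trip
    preserves coordinates well beyond 1e-9.
    """
    placements = list(placements)
    ks = {len(p.coords) for p in placements}
    if len(ks) > 1:
        raise ValueError(f"placements mix different K values: {sorted(ks)}")
    k = ks.pop() if ks else 0

    def fmt(x: float) -> str:
        return "nan" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.12g}"

    with open(path, "w") as fh:
        cols = ["sample_id", "L_used", "t", "Z"]
        cols += [f"PC{i + 1}" for i in range(k)]
        cols += ["knn_top_population", "knn_top_fraction"]
        fh.write("\t".join(cols) + "\n")
        for p in placements:
            z = p.Z if p.Z is not None else float("nan")
            if p.knn:
                top_pop, top_frac = max(p.knn.items(), key=lambda kv: (kv[1], kv[0]))
            else:
                top_pop, top_frac = "NA", float("nan")
            row = [str(p.sample_id), str(p.L_used), fmt(p.t), fmt(z)]
            row += [fmt(c) for c in p.coords]
            row += [str(top_pop), fmt(top_frac)]
            fh.write("\t".join(row) + "\n")


def read_placements(path: str | Path) -> pd.DataFrame:
    """Read a placement table back as a DataFrame (round-trip convenience)."""
    return pd.read_csv(path, sep="\t")
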