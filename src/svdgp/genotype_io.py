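"""Genotype and phenotype input, validation, centering and standardization.

Genotypes are held as an N x k dosage matrix (individuals x loci) together
with per-locus allele frequencies of the '1' allele and a chromosome label
per locus.  Three codings are tracked explicitly: ``raw`` (dosages in
[0, 2]), ``centered`` (dosage - 2p) and ``standardized``
((dosage - 2p) / sqrt(2p(1-p))).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CODINGS = ("raw", "centered", "standardized")


@dataclass
class GenotypeMatrix:
    """Dosage matrix with allele-frequency and chromosome bookkeeping."""

    dosages: np.ndarray
    ids: np.ndarray
    snp_ids: np.ndarray
    allele_freq: np.ndarray
    chrom_of: np.ndarray
    coding: str = "raw"
    freq_source: str = "self"

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (individuals x loci) array")
        n, k = self.dosages.shape
        self.ids = np.asarray(self.ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.allele_freq = np.asarray(self.allele_freq, dtype=float)
        self.chrom_of = np.asarray(self.chrom_of, dtype=object)
        if len(self.ids) != n:
            raise ValueError(f"{len(self.ids)} ids for {n} rows")
        for name, arr in (("snp_ids", self.snp_ids),
                          ("allele_freq", self.allele_freq),
                          ("chrom_of", self.chrom_of)):
            if len(arr) != k:
                raise ValueError(f"{name} has length {len(arr)}, expected {k}")
        if self.coding not in CODINGS:
            raise ValueError(f"unknown coding {self.coding!r}")
        if np.any(self.allele_freq < -1e-12) or np.any(self.allele_freq > 1 + 1e-12):
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def monomorphic(self) -> np.ndarray:
        """Boolean mask of loci with allele frequency 0 or 1."""
        p = self.allele_freq
        return (p <= 0.0) | (p >= 1.0)

    @property
    def chromosomes(self) -> list:
        """Sorted unique chromosome labels (deterministic merge order)."""
        return sorted(set(self.chrom_of.tolist()), key=str)

    def subset_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(self, dosages=self.dosages[index], ids=self.ids[index])


@dataclass
class PhenotypeVector:
    y: np.ndarray
    ids: np.ndarray = None
    mean_mu: float | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.ids is None:
            self.ids = np.arange(len(self.y)).astype(object)
        self.ids = np.asarray(self.ids, dtype=object)
        if len(self.ids) != len(self.y):
            raise ValueError("ids and y length mismatch")


@dataclass
class VarianceComponents:
    """Variance components driving the ridge ratios.

    ``sigma_m2`` (per-marker effect variance) defaults to sigma_g2 / rho with
    rho = 2 * sum p_i (1 - p_i); pass it explicitly to override.
    """

    sigma_g2: float
    sigma_e2: float
    sigma_m2: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_g2 <= 0 or self.sigma_e2 <= 0:
            raise ValueError("variances must be positive")
        if self.sigma_m2 is not None and self.sigma_m2 <= 0:
            raise ValueError("sigma_m2 must be positive")

    @classmethod
    def from_h2(cls, h2: float, sigma_p2: float = 1.0) -> "VarianceComponents":
        if not 0 < h2 < 1:
            raise ValueError("h2 must be in (0, 1)")
        return cls(sigma_g2=h2 * sigma_p2, sigma_e2=(1 - h2) * sigma_p2)

    @property
    def h2(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)

    @property
    def lambda_g(self) -> float:
        """Ridge ratio for the animal model: sigma_e2 / sigma_g2."""
        return self.sigma_e2 / self.sigma_g2

    def lambda_snp(self, rho_val: float) -> float:
        """Ridge ratio for marker models: sigma_e2 / sigma_m2."""
        sm2 = self.sigma_m2 if self.sigma_m2 is not None else self.sigma_g2 / rho_val
        return self.sigma_e2 / sm2


def rho(gm: GenotypeMatrix, weights: np.ndarray | None = None) -> float:
    """Scaling constant 2 p'(1-p), or 2 p'D(1-p) with per-locus weights."""
    p = gm.allele_freq
    if weights is None:
        return float(2.0 * np.sum(p * (1.0 - p)))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != p.shape:
        raise ValueError("weights must have one entry per locus")
    return float(2.0 * np.sum(weights * p * (1.0 - p)))


def scaling_constant(gm: GenotypeMatrix) -> float:
    """Default GRM denominator for the matrix coding.

    Centered dosages pair with 2 sum p(1-p); standardized dosages already
    carry unit per-locus variance, so the denominator is the locus count.
    """
    if gm.coding == "standardized":
        return float(gm.n_loci)
    return rho(gm)


def vanraden2_weights(p: np.ndarray) -> np.ndarray:
    """Per-locus weights 1 / (2 p (1-p)); monomorphic loci are invalid."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("weights undefined for monomorphic loci")
    return 1.0 / (2.0 * p * (1.0 - p))


def center(
    gm: GenotypeMatrix,
    freq_source: str = "self",
    allele_freq: np.ndarray | None = None,
    core_ids: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Return a column-centered copy (dosage - 2p).

    freq_source 'self' recomputes p from all rows, 'core' from the rows in
    ``core_ids``, 'supplied' uses ``allele_freq`` as given.  Re-centering an
    already centered/standardized matrix is rejected rather than silently
    applied twice.
    """
    if gm.coding != "raw":
        raise ValueError(f"cannot center a matrix with coding {gm.coding!r}")
    if freq_source == "self":
        p = gm.dosages.mean(axis=0) / 2.0
    elif freq_source == "core":
        if core_ids is None:
            raise ValueError("freq_source='core' requires core_ids")
        mask = np.isin(gm.ids, np.asarray(core_ids, dtype=object))
        if not mask.any():
            raise ValueError("no core individuals found in genotype matrix")
        p = gm.dosages[mask].mean(axis=0) / 2.0
    elif freq_source == "supplied":
        if allele_freq is None:
            raise ValueError("freq_source='supplied' requires allele_freq")
        p = np.asarray(allele_freq, dtype=float)
    else:
        raise ValueError(f"unknown freq_source {freq_source!r}")
    n_mono = int(((p <= 0) | (p >= 1)).sum())
    if n_mono:
        logger.info("centering kept %d monomorphic loci as zero columns", n_mono)
    return replace(gm, dosages=gm.dosages - 2.0 * p, allele_freq=p,
                   coding="centered", freq_source=freq_source)


def standardize(
    gm: GenotypeMatrix,
    freq_source: str = "self",
    allele_freq: np.ndarray | None = None,
    core_ids: np.ndarray | None = None,
    drop_monomorphic: bool = False,
) -> GenotypeMatrix:
    """Return a standardized copy: (dosage - 2p) / sqrt(2 p (1-p))."""
    centered = center(gm, freq_source=freq_source, allele_freq=allele_freq,
                      core_ids=core_ids)
    p = centered.allele_freq
    mono = (p <= 0) | (p >= 1)
    if mono.any():
        if not drop_monomorphic:
            raise ValueError(
                f"monomorphic locus cannot be standardized "
                f"({int(mono.sum())} loci with p in {{0,1}}); "
                "drop them first or pass drop_monomorphic=True")
        logger.info("dropping %d monomorphic loci before standardization",
                    int(mono.sum()))
        keep = ~mono
        centered = replace(centered, dosages=centered.dosages[:, keep],
                           snp_ids=centered.snp_ids[keep], allele_freq=p[keep],
                           chrom_of=centered.chrom_of[keep])
        p = centered.allele_freq
    scale = np.sqrt(2.0 * p * (1.0 - p))
    return replace(centered, dosages=centered.dosages / scale,
                   coding="standardized")


def filter_maf(gm: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Drop loci whose minor allele frequency is below ``min_maf``."""
    maf = np.minimum(gm.allele_freq, 1.0 - gm.allele_freq)
    keep = maf >= min_maf
    return replace(gm, dosages=gm.dosages[:, keep], snp_ids=gm.snp_ids[keep],
                   allele_freq=gm.allele_freq[keep],
                   chrom_of=gm.chrom_of[keep])


def drop_monomorphic(gm: GenotypeMatrix) -> GenotypeMatrix:
    keep = ~gm.monomorphic
    return replace(gm, dosages=gm.dosages[:, keep], snp_ids=gm.snp_ids[keep],
                   allele_freq=gm.allele_freq[keep], chrom_of=gm.chrom_of[keep])


# ---------------------------------------------------------------------------
# readers


def _finish_matrix(dosages, ids, snp_ids, chroms, coding, allele_freq,
                   impute_missing):
    dosages = np.asarray(dosages, dtype=float)
    if np.isnan(dosages).any():
        if not impute_missing:
            raise ValueError("missing genotypes present; "
                             "pass impute_missing=True for mean imputation")
        col_mean = np.nanmean(dosages, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(np.isnan(dosages))
        dosages[idx] = col_mean[idx[1]]
    if allele_freq is None:
        allele_freq = dosages.mean(axis=0) / 2.0 if coding == "raw" else \
            np.full(dosages.shape[1], 0.5)
    if coding == "raw" and (dosages.min(initial=0) < 0 or dosages.max(initial=0) > 2):
        raise ValueError("raw dosages must lie in [0, 2]")
    return GenotypeMatrix(dosages, ids, snp_ids, allele_freq, chroms, coding)


def read_chromosome_map(path) -> dict:
    """Sidecar TSV `snp_id<TAB>chrom` -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["snp_id", "chrom"],
                     dtype=str, comment="#")
    return dict(zip(df["snp_id"], df["chrom"]))


def _map_chroms(snp_ids, chrom_map):
    if chrom_map is None:
        return np.full(len(snp_ids), "1", dtype=object)
    missing = [s for s in snp_ids if s not in chrom_map]
    if missing:
        raise ValueError(f"{len(missing)} loci missing from chromosome map "
                         f"(first: {missing[0]!r})")
    return np.array([chrom_map[s] for s in snp_ids], dtype=object)


def read_genotypes(
    path,
    format: str = "tsv",
    coding: str = "raw",
    chrom_map: dict | str | None = None,
    allele_freq: np.ndarray | None = None,
    impute_missing: bool = False,
) -> GenotypeMatrix:
    """Read a genotype matrix from TSV, PLINK .raw dialect, or VCF.

    ``coding`` overrides the coding attached to file contents (worked
    examples ship matrices that are already centered).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if isinstance(chrom_map, (str, Path)):
        chrom_map = read_chromosome_map(chrom_map)

    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        ids = df.iloc[:, 0].astype(str).to_numpy(dtype=object)
        snp_ids = np.array(df.columns[1:], dtype=object)
        dosages = df.iloc[:, 1:].to_numpy(dtype=float)
        chroms = _map_chroms(snp_ids, chrom_map)
        return _finish_matrix(dosages, ids, snp_ids, chroms, coding,
                              allele_freq, impute_missing)

    if format == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+")
        lead = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        if list(df.columns[:6]) != lead:
            raise ValueError("not a PLINK .raw file (expected FID IID PAT MAT "
                             "SEX PHENOTYPE leader columns)")
        ids = df["IID"].astype(str).to_numpy(dtype=object)
        snp_ids = np.array(df.columns[6:], dtype=object)
        dosages = df.iloc[:, 6:].to_numpy(dtype=float)
        chroms = _map_chroms(snp_ids, chrom_map)
        return _finish_matrix(dosages, ids, snp_ids, chroms, coding,
                              allele_freq, impute_missing)

    if format == "vcf":
        return _read_vcf(path, coding, allele_freq, impute_missing)

    raise ValueError(f"unknown format {format!r}")


def _read_vcf(path, coding, allele_freq, impute_missing):
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - env without cyvcf2
        raise ImportError("VCF input requires cyvcf2") from exc
    vcf = VCF(str(path))
    ids = np.array(vcf.samples, dtype=object)
    cols, snp_ids, chroms = [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gt = np.asarray(var.genotype.array(), dtype=float)[:, :2]
            col = np.where((gt < 0).any(axis=1), np.nan, gt.clip(min=0).sum(axis=1))
        cols.append(col)
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM))
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-biallelic VCF records")
    dosages = np.column_stack(cols) if cols else np.zeros((len(ids), 0))
    return _finish_matrix(dosages, ids, np.array(snp_ids, dtype=object),
                          np.array(chroms, dtype=object), coding, allele_freq,
                          impute_missing)


def read_phenotypes(path) -> PhenotypeVector:
    """TSV with columns `id  value` (header optional)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("phenotype file needs `id` and `value` columns")
    return PhenotypeVector(y=df.iloc[:, 1].to_numpy(dtype=float),
                           ids=df.iloc[:, 0].astype(str).to_numpy(dtype=object))


def align_phenotypes(gm: GenotypeMatrix, pheno: PhenotypeVector) -> np.ndarray:
    """Join phenotypes on ids, returning y in genotype row order."""
    lookup = {i: v for i, v in zip(pheno.ids, pheno.y)}
    missing = [i for i in gm.ids if i not in lookup]
    if missing:
        raise ValueError(f"{len(missing)} genotyped individuals lack "
                         f"phenotypes (first: {missing[0]!r})")
    return np.array([lookup[i] for i in gm.ids], dtype=float)
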