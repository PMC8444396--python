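"""Genotype and methylation QC filters.

SNP-level rules: Hardy-Weinberg exact test, missingness, minor-allele
frequency. Sample-level missingness is applied first, then SNP rules,
mirroring the conventional PLINK-style order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from comethqtl.io_formats import GenotypeMatrix, MethylationMatrix

logger = logging.getLogger(__name__)

SEX_CHROMOSOMES = {"X", "Y", "23", "24"}


@dataclass
class QCParams:
    """Thresholds for genotype and CpG filtering."""

    hwe_p_cutoff: float = 0.001
    snp_max_missing: float = 0.10
    min_maf: float = 0.05
    sample_max_missing: float = 0.05
    drop_sex_chromosomes: bool = True

    def __post_init__(self) -> None:
        for name in ("hwe_p_cutoff", "snp_max_missing", "min_maf",
                     "sample_max_missing"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided Hardy-Weinberg exact test (Wigginton et al. style).

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote-count configuration whose probability does not exceed
    that of the observed one. The standard (not mid-p) version is used.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het  # copies of the rarer allele
    # Valid het counts share the parity of the rare-allele count.
    het_values = list(range(n_rare % 2, n_rare + 1, 2))
    if not het_values:
        return 1.0
    # Unnormalized probabilities via the recurrence
    # P(h+2)/P(h) = 4*hom_rare*hom_common / ((h+2)*(h+1)),
    # computed outward from the mode for numerical stability.
    probs = {}
    mid = n_rare * (2 * n - n_rare) / (2 * n - 1) if n > 0 else 0
    h_mode = int(mid)
    if (h_mode % 2) != (n_rare % 2):
        h_mode += 1
    h_mode = min(max(h_mode, het_values[0]), het_values[-1])
    probs[h_mode] = 1.0
    h = h_mode
    while h - 2 >= het_values[0]:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
    h = h_mode
    while h + 2 <= het_values[-1]:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2) * (h + 1))
        h += 2
    total = sum(probs.values())
    p_obs = probs[n_het] / total
    p_value = sum(p for p in probs.values() if p / total <= p_obs * (1 + 1e-12))
    return min(p_value / total, 1.0)


def minor_allele_frequency(dosage_row: np.ndarray) -> float:
    """MAF from a 0/1/2 dosage vector, ignoring missing entries."""
    dosage_row = np.asarray(dosage_row, dtype=float)
    mask = np.isfinite(dosage_row)
    if not mask.any():
        raise ValueError("all dosages missing")
    p = dosage_row[mask].sum() / (2.0 * mask.sum())
    return min(p, 1.0 - p)


@dataclass
class QCReport:
    """Counts of items removed by each rule."""

    n_samples_in: int = 0
    n_snps_in: int = 0
    samples_removed_missing: int = 0
    snps_removed_hwe: int = 0
    snps_removed_missing: int = 0
    snps_removed_maf: int = 0
    snps_removed_sex_chrom: int = 0
    n_samples_out: int = 0
    n_snps_out: int = 0
    removed_sample_ids: list[str] = field(default_factory=list)
    removed_snp_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            k: v
            for k, v in self.__dict__.items()
            if not k.startswith("removed_")
        }


def genotype_counts(dosage_row: np.ndarray) -> tuple[int, int, int]:
    row = np.asarray(dosage_row, dtype=float)
    row = row[np.isfinite(row)]
    return int((row == 0).sum()), int((row == 1).sum()), int((row == 2).sum())


def filter_genotypes(
    genotypes: GenotypeMatrix, params: QCParams | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply sample-then-SNP QC.

    Order: (1) drop samples with more than ``sample_max_missing`` missing
    dosages; (2) drop SNPs failing the HWE exact test at ``hwe_p_cutoff``,
    exceeding ``snp_max_missing`` missingness, or below ``min_maf``; sex
    chromosomes optionally removed. Raises if no SNP survives.
    """
    params = params or QCParams()
    report = QCReport(n_samples_in=genotypes.n_samples, n_snps_in=genotypes.n_snps)

    missing_frac = np.mean(~np.isfinite(genotypes.dosage), axis=0)
    keep_samples = [
        s
        for s, frac in zip(genotypes.sample_ids, missing_frac)
        if frac <= params.sample_max_missing
    ]
    report.removed_sample_ids = [
        s for s in genotypes.sample_ids if s not in set(keep_samples)
    ]
    report.samples_removed_missing = len(report.removed_sample_ids)
    gt = genotypes.subset_samples(keep_samples)

    keep_snps = []
    for i, snp in enumerate(gt.snp_ids):
        row = gt.dosage[i]
        if params.drop_sex_chromosomes and str(gt.chrom[i]).upper() in SEX_CHROMOSOMES:
            report.snps_removed_sex_chrom += 1
            report.removed_snp_ids.append(snp)
            continue
        miss = np.mean(~np.isfinite(row)) if row.size else 1.0
        if miss > params.snp_max_missing:
            report.snps_removed_missing += 1
            report.removed_snp_ids.append(snp)
            continue
        finite = row[np.isfinite(row)]
        if finite.size == 0:
            report.snps_removed_missing += 1
            report.removed_snp_ids.append(snp)
            continue
        if minor_allele_frequency(row) < params.min_maf:
            report.snps_removed_maf += 1
            report.removed_snp_ids.append(snp)
            continue
        aa, ab, bb = genotype_counts(row)
        if hwe_exact_test(aa, ab, bb) < params.hwe_p_cutoff:
            report.snps_removed_hwe += 1
            report.removed_snp_ids.append(snp)
            continue
        keep_snps.append(snp)

    report.n_samples_out = gt.n_samples
    report.n_snps_out = len(keep_snps)
    if not keep_snps:
        err = ValueError("no SNPs survive QC")
        err.report = report  # type: ignore[attr-defined]
        raise err
    return gt.subset_snps(keep_snps), report


def filter_cpgs(
    methylation: MethylationMatrix,
    mask_cpg_ids: list[str] | None = None,
    params: QCParams | None = None,
) -> MethylationMatrix:
    """Remove masked CpG ids and, if configured, sex-chromosome CpGs.

    Mask ids absent from the matrix are counted and logged, never an error.
    """
    params = params or QCParams()
    mask = set(mask_cpg_ids or [])
    present = set(methylation.cpg_ids)
    absent = mask - present
    if absent:
        logger.warning("%d masked CpG ids not present in the matrix", len(absent))
    keep = []
    for i, cpg in enumerate(methylation.cpg_ids):
        if cpg in mask:
            continue
        if (
            params.drop_sex_chromosomes
            and str(methylation.chrom[i]).upper() in SEX_CHROMOSOMES
        ):
            continue
        keep.append(cpg)
    if not keep:
        logger.warning("all CpGs removed by filtering")
    return methylation.subset_cpgs(keep)
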