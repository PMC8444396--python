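"""Tag-CpG selection, cis association testing, and significance cutoffs.

One ordinary-least-squares fit per (tag-CpG, candidate SNP) pair:
beta ~ intercept + dosage + covariates, with complete-case removal per
pair. The genome-wide cutoff is a Bonferroni-style correction over the
total number of blocks times the average number of cis SNPs per tag-CpG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from comethqtl.correlation_blocks import CorrelationBlock
from comethqtl.io_formats import (
    METHQTL_COLUMNS,
    CovariateTable,
    GenotypeMatrix,
    MethylationMatrix,
)

logger = logging.getLogger(__name__)


@dataclass
class AssocParams:
    cis_window: int = 500_000
    alpha: float = 0.05
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cis_window <= 0:
            raise ValueError("cis_window must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class MethQTLRecord:
    """One CpG-SNP association: slope is change in beta per alt-allele dose."""

    cpg_id: str
    snp_id: str
    chrom: str
    cpg_pos: int
    snp_pos: int
    distance: int  # snp_pos - cpg_pos, signed
    slope: float
    se: float
    p_value: float
    n_samples: int


class AssociationSkipped(Exception):
    """A pair that cannot be fit; ``reason`` explains why."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def select_tag_cpg(
    block: CorrelationBlock,
    methylation: MethylationMatrix,
    method: str = "medoid-of-medians",
) -> str:
    """Pick the representative CpG of a block.

    Default: compute each CpG's median beta across samples and return the
    CpG whose median is the median of that vector, taking the lower of the
    two central values for even-sized blocks and breaking ties by smallest
    genomic position. All-missing CpGs are excluded from candidacy.
    """
    if not block.member_cpg_ids:
        raise ValueError("empty block")
    index = {c: i for i, c in enumerate(methylation.cpg_ids)}
    candidates = []
    for cpg in block.member_cpg_ids:
        row = methylation.beta[index[cpg]]
        if not np.isfinite(row).any():
            logger.warning("CpG %s is all-missing; excluded from tag candidacy", cpg)
            continue
        candidates.append((cpg, float(np.nanmedian(row)), int(methylation.pos[index[cpg]])))
    if not candidates:
        raise ValueError(f"no usable CpG in block on {block.chrom}")
    if method == "first":
        return min(candidates, key=lambda t: t[2])[0]
    if method == "mean-center":
        means = {
            cpg: float(np.nanmean(methylation.beta[index[cpg]]))
            for cpg, _, _ in candidates
        }
        center = float(np.mean(list(means.values())))
        return min(candidates, key=lambda t: (abs(means[t[0]] - center), t[2]))[0]
    if method != "medoid-of-medians":
        raise ValueError(f"unknown tag selection method {method!r}")
    medians = sorted(m for _, m, _ in candidates)
    target = medians[(len(medians) - 1) // 2]  # lower median for even sizes
    ties = [(cpg, pos) for cpg, m, pos in candidates if m == target]
    return min(ties, key=lambda t: t[1])[0]


def cis_candidates(
    tag_cpg_pos: int,
    tag_chrom: str,
    genotypes: GenotypeMatrix,
    cis_window: int = 500_000,
) -> list[str]:
    """SNPs on the tag's chromosome strictly closer than ``cis_window`` bp."""
    on_chrom = genotypes.chrom == str(tag_chrom)
    close = np.abs(genotypes.pos - int(tag_cpg_pos)) < cis_window
    return [s for s, keep in zip(genotypes.snp_ids, on_chrom & close) if keep]


def fit_association(
    meth_vector: np.ndarray,
    dosage_vector: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> tuple[float, float, float, int]:
    """OLS of methylation on [intercept, dosage, covariates].

    ``covariates`` must already be numeric (indicator-expanded), aligned to
    the same sample order as the two vectors. Complete cases only. Returns
    (slope, se, p_value, n) for the dosage coefficient; the p-value is
    two-sided from the t distribution with n - k degrees of freedom.
    """
    y = np.asarray(meth_vector, dtype=float)
    g = np.asarray(dosage_vector, dtype=float)
    if y.shape != g.shape:
        raise ValueError("methylation and dosage vectors differ in length")
    cov = None
    if covariates is not None and covariates.shape[1] > 0:
        cov = np.asarray(covariates, dtype=float)
        if cov.shape[0] != y.shape[0]:
            raise ValueError("covariate rows do not match sample count")
    complete = np.isfinite(y) & np.isfinite(g)
    if cov is not None:
        complete &= np.isfinite(cov).all(axis=1)
    y, g = y[complete], g[complete]
    X = g[:, None] if cov is None else np.column_stack([g, cov[complete]])
    n, k = X.shape[0], X.shape[1] + 1  # + intercept
    if n <= k:
        raise AssociationSkipped("insufficient-complete-cases")
    if np.ptp(g) == 0:
        raise AssociationSkipped("monomorphic-in-subset")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise AssociationSkipped("rank-deficient-design")
    fit = sm.OLS(y, design).fit()
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    p_value = float(fit.pvalues[1])
    return slope, se, max(p_value, np.nextafter(0, 1)), n


def call_methqtls(
    methylation: MethylationMatrix,
    genotypes: GenotypeMatrix,
    covariates: CovariateTable | None,
    blocks: list[CorrelationBlock],
    params: AssocParams | None = None,
) -> pd.DataFrame:
    """Fit every (tag-CpG, cis SNP) pair and return the full summary table.

    Samples are aligned by id intersection across all inputs. Pairs that
    cannot be fit (monomorphic in the complete-case subset, rank-deficient)
    are skipped and counted, never silently dropped.
    """
    params = params or AssocParams()
    shared = [s for s in methylation.sample_ids if s in set(genotypes.sample_ids)]
    if covariates is not None:
        shared = [s for s in shared if s in set(covariates.sample_ids)]
    if not shared:
        raise ValueError("no overlapping samples between inputs")
    meth = methylation.subset_samples(shared)
    geno = genotypes.subset_samples(shared)
    cov_design = None
    if covariates is not None and params.covariate_names:
        cov_design = covariates.design_columns(params.covariate_names).loc[shared]

    cpg_index = {c: i for i, c in enumerate(meth.cpg_ids)}
    snp_index = {s: i for i, s in enumerate(geno.snp_ids)}
    records = []
    n_skipped: dict[str, int] = {}
    for block in blocks:
        tag = block.tag_cpg_id or select_tag_cpg(block, meth)
        ti = cpg_index[tag]
        tag_pos = int(meth.pos[ti])
        snps = cis_candidates(tag_pos, block.chrom, geno, params.cis_window)
        if not snps:
            logger.warning("no cis SNPs within %d bp of tag %s", params.cis_window, tag)
            continue
        y = meth.beta[ti]
        for snp in snps:
            si = snp_index[snp]
            try:
                slope, se, p, n = fit_association(y, geno.dosage[si], cov_design)
            except AssociationSkipped as skip:
                n_skipped[skip.reason] = n_skipped.get(skip.reason, 0) + 1
                continue
            snp_pos = int(geno.pos[si])
            records.append(
                MethQTLRecord(
                    cpg_id=tag,
                    snp_id=snp,
                    chrom=block.chrom,
                    cpg_pos=tag_pos,
                    snp_pos=snp_pos,
                    distance=snp_pos - tag_pos,
                    slope=slope,
                    se=se,
                    p_value=p,
                    n_samples=n,
                )
            )
    if n_skipped:
        logger.info("skipped pairs by reason: %s", n_skipped)
    df = pd.DataFrame([r.__dict__ for r in records], columns=METHQTL_COLUMNS)
    df.attrs["n_skipped"] = n_skipped
    return df


def genome_wide_cutoff(
    block_counts: list[int], mean_snps_per_cpg: float, alpha: float = 0.05
) -> float:
    """alpha / (total correlation blocks x mean cis SNPs per tag-CpG)."""
    total = sum(block_counts)
    denom = total * mean_snps_per_cpg
    if denom <= 0:
        raise ValueError("cutoff denominator must be positive")
    return alpha / denom


def replication_cutoff(methqtl_counts: list[int], alpha: float = 0.05) -> float:
    """alpha / total number of discovery methQTLs across analyses."""
    total = sum(methqtl_counts)
    if total <= 0:
        raise ValueError("total methQTL count must be positive")
    return alpha / total


def mean_cis_candidates(records: pd.DataFrame) -> float:
    """Rounded mean number of tested SNPs per tag-CpG in a summary table."""
    if records.empty:
        raise ValueError("empty summary table")
    return float(round(records.groupby("cpg_id").size().mean()))


def select_lead_snps(records: pd.DataFrame) -> pd.DataFrame:
    """Keep, per CpG, the record with the smallest p-value.

    Ties broken by smaller absolute distance, then lexicographic SNP id.
    """
    if records.empty:
        raise ValueError("empty methQTL table")
    ordered = records.assign(_absdist=records["distance"].abs()).sort_values(
        ["cpg_id", "p_value", "_absdist", "snp_id"], kind="mergesort"
    )
    lead = ordered.groupby("cpg_id", sort=True).head(1).drop(columns="_absdist")
    return lead.reset_index(drop=True)
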