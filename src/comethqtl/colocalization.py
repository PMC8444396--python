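"""Cross-tissue colocalization of methQTLs via SMR and HEIDI.

A CpG that is a tag in at least two tissues with a genome-wide-significant
lead SNP in at least one of them is tested pairwise against every other
tissue where it is a tag. The anchor tissue is the one with the smallest
lead p-value. Per pair, the SMR test asks whether the two tissues share an
association at the anchor's lead SNP; the HEIDI test asks whether a shared
association reflects one pleiotropic variant or linkage of distinct
variants.

Statistic forms
---------------
SMR: with z_a = slope_a / se_a and z_b = slope_b / se_b,

    T_smr = z_a^2 z_b^2 / (z_a^2 + z_b^2),  p from chi-square(1).

HEIDI: for instrument SNP i, the cross-tissue effect ratio is
b_i = slope_b,i / slope_a,i. Under pleiotropy all b_i estimate the same
quantity, so d_i = b_i - b_lead has mean zero. Delta-method (first-order)
variances, with within-tissue correlations between SNP effect estimates
approximated by the LD correlation r:

    cov(b_i, b_j) = r_ij * [ se_b,i se_b,j / (a_i a_j)
                             + s_i s_j se_a,i se_a,j / (a_i^2 a_j^2) ]

where a = slope_a, s = slope_b (var is the i = j case). The statistic is
the sum of squared standardized d_i; its null distribution, a sum of
correlated 1-df chi-squares, is approximated by two-moment matching on the
eigenvalues of the correlation matrix of the standardized differences
(Satterthwaite-style fallback when the decomposition fails). A small
HEIDI p indicates heterogeneity, i.e. linkage rather than pleiotropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from comethqtl.io_formats import GenotypeMatrix

logger = logging.getLogger(__name__)

COLOC_COLUMNS = [
    "cpg_id",
    "anchor_tissue",
    "other_tissue",
    "lead_snp",
    "smr_stat",
    "smr_p",
    "smr_fdr",
    "heidi_stat",
    "heidi_p",
    "heidi_m",
    "heidi_skipped",
    "verdict",
]


@dataclass
class ColocParams:
    smr_fdr_cutoff: float = 0.05
    heidi_p_cutoff: float = 0.05  # paper also reports results at 0.001
    heidi_min_snps: int = 3
    heidi_max_snps: int = 20
    instrument_z2_min: float = 10.0  # chi-square(1) inclusion threshold
    ld_prune_r2: float = 0.9  # drop instruments in near-perfect LD with lead

    def __post_init__(self) -> None:
        for name in ("smr_fdr_cutoff", "heidi_p_cutoff"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name}={value} outside (0, 1)")


@dataclass
class TissueSummary:
    """Per-tissue methQTL summaries needed for colocalization.

    ``lead``: one row per tag-CpG (lead-SNP record, methQTL table columns).
    ``cis``: full per-(CpG, SNP) summary statistics for the HEIDI SNP sets.
    """

    tissue: str
    lead: pd.DataFrame
    cis: pd.DataFrame

    def __post_init__(self) -> None:
        if self.lead["cpg_id"].duplicated().any():
            raise ValueError(f"{self.tissue}: more than one lead record per CpG")

    def lead_for(self, cpg_id: str) -> pd.Series | None:
        hit = self.lead[self.lead["cpg_id"] == cpg_id]
        return None if hit.empty else hit.iloc[0]

    def stats_for(self, cpg_id: str, snp_id: str) -> pd.Series | None:
        hit = self.cis[(self.cis["cpg_id"] == cpg_id) & (self.cis["snp_id"] == snp_id)]
        return None if hit.empty else hit.iloc[0]


@dataclass
class ColocTest:
    cpg_id: str
    anchor_tissue: str
    other_tissue: str
    lead_snp: str


def smr_test(
    slope_a: float, se_a: float, slope_b: float, se_b: float
) -> tuple[float, float]:
    """SMR chi-square(1) statistic and p-value; symmetric in (a, b)."""
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    z_a2 = (slope_a / se_a) ** 2
    z_b2 = (slope_b / se_b) ** 2
    if z_a2 == 0 and z_b2 == 0:
        logger.warning("degenerate SMR input: both z-scores zero")
        return 0.0, 1.0
    stat = z_a2 * z_b2 / (z_a2 + z_b2)
    return float(stat), float(stats.chi2.sf(stat, df=1))


def ld_matrix(genotypes: GenotypeMatrix, snp_ids: list[str]) -> pd.DataFrame:
    """Pairwise Pearson correlation of dosages (pairwise-complete)."""
    idx = [genotypes.snp_ids.index(s) for s in snp_ids]
    df = pd.DataFrame(genotypes.dosage[idx].T, columns=snp_ids)
    return df.corr(method="pearson", min_periods=3).fillna(0.0)


def _ratio_covariance(
    a: np.ndarray,
    se_a: np.ndarray,
    s: np.ndarray,
    se_b: np.ndarray,
    r: np.ndarray,
    lead: int = 0,
) -> np.ndarray:
    """Delta-method covariance of the effect ratios b_i = s_i / a_i.

    Only the residual-noise component of each slope's error is shared
    between SNPs in LD; the LD-estimation component (which grows with the
    causal effect) is not. The shared component per SNP is therefore capped
    at the lead SNP's standard error for the cross terms, while marginal
    variances keep the full standard errors.
    """
    shared_a = np.minimum(se_a, se_a[lead])
    shared_b = np.minimum(se_b, se_b[lead])
    term_b = np.outer(shared_b, shared_b) / np.outer(a, a)
    term_a = np.outer(s * shared_a, s * shared_a) / np.outer(a**2, a**2)
    cov = r * (term_b + term_a)
    np.fill_diagonal(cov, se_b**2 / a**2 + s**2 * se_a**2 / a**4)
    return cov


def heidi_test(
    slopes_a: np.ndarray,
    ses_a: np.ndarray,
    slopes_b: np.ndarray,
    ses_b: np.ndarray,
    ld: np.ndarray,
    lead_index: int,
    params: ColocParams | None = None,
) -> tuple[float, float, int]:
    """HEIDI heterogeneity test over a set of instrument SNPs.

    Inputs are per-SNP summary statistics in the anchor (a) and other (b)
    tissues, the LD correlation matrix over the same SNPs, and the index of
    the lead SNP. Instruments are the non-lead SNPs with anchor z^2 above
    ``instrument_z2_min`` that are not in near-perfect LD with the lead,
    capped at ``heidi_max_snps`` by descending anchor z^2. Returns
    (stat, p, m); (nan, nan, 0) when fewer than ``heidi_min_snps``
    instruments remain.
    """
    params = params or ColocParams()
    slopes_a = np.asarray(slopes_a, dtype=float)
    ses_a = np.asarray(ses_a, dtype=float)
    slopes_b = np.asarray(slopes_b, dtype=float)
    ses_b = np.asarray(ses_b, dtype=float)
    ld = np.asarray(ld, dtype=float)
    n = slopes_a.size
    if not 0 <= lead_index < n:
        raise ValueError("lead_index out of range")
    if np.any(ses_a <= 0) or np.any(ses_b <= 0):
        raise ValueError("standard errors must be positive")

    z2 = (slopes_a / ses_a) ** 2
    eligible = [
        i
        for i in range(n)
        if i != lead_index
        and z2[i] >= params.instrument_z2_min
        and ld[i, lead_index] ** 2 <= params.ld_prune_r2
    ]
    eligible.sort(key=lambda i: -z2[i])
    instruments = eligible[: params.heidi_max_snps]
    m = len(instruments)
    if m < params.heidi_min_snps:
        return float("nan"), float("nan"), 0

    sel = [lead_index] + instruments  # lead first
    a, sa = slopes_a[sel], ses_a[sel]
    s, sb = slopes_b[sel], ses_b[sel]
    r = ld[np.ix_(sel, sel)]
    cov_b = _ratio_covariance(a, sa, s, sb, r, lead=0)

    b = s / a
    d = b[1:] - b[0]
    # cov(d_i, d_j) = cov(b_i, b_j) - cov(b_i, b_L) - cov(b_j, b_L) + var(b_L)
    cov_d = (
        cov_b[1:, 1:]
        - cov_b[1:, :1]
        - cov_b[:1, 1:]
        + cov_b[0, 0]
    )
    sd = np.sqrt(np.diag(cov_d))
    z_d = d / sd
    stat = float(np.sum(z_d**2))
    corr_d = cov_d / np.outer(sd, sd)
    try:
        eigvals = np.linalg.eigvalsh(corr_d)
        eigvals = np.clip(eigvals, 0.0, None)
        lam_sum = float(eigvals.sum())
        lam_sq = float((eigvals**2).sum())
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate inputs
        lam_sum, lam_sq = float(m), float(m)
    if lam_sq <= 0:
        return stat, 1.0, m
    # Two-moment match: stat ~ g * chi2(h) with g = sum(l^2)/sum(l),
    # h = sum(l)^2 / sum(l^2).
    g = lam_sq / lam_sum
    h = lam_sum**2 / lam_sq
    p = float(stats.chi2.sf(stat / g, df=h))
    return stat, max(p, np.nextafter(0, 1)), m


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return p_values.copy()
    return multipletests(p_values, method="fdr_bh")[1]


def select_coloc_tests(
    summaries: list[TissueSummary], genome_wide_cutoff: float
) -> list[ColocTest]:
    """Enumerate the pairwise tests implied by the selection rules.

    A CpG qualifies if it is a tag-CpG in at least two tissues and its lead
    p-value is below the cutoff in at least one. The anchor is the tissue
    with the smallest lead p-value; one test per (CpG, anchor, other) pair.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two tissues")
    presence: dict[str, list[tuple[float, str]]] = {}
    for summary in summaries:
        for _, row in summary.lead.iterrows():
            presence.setdefault(row["cpg_id"], []).append(
                (float(row["p_value"]), summary.tissue)
            )
    lead_of = {s.tissue: s for s in summaries}
    tests = []
    for cpg_id in sorted(presence):
        entries = sorted(presence[cpg_id])
        if len(entries) < 2 or entries[0][0] >= genome_wide_cutoff:
            continue
        anchor = entries[0][1]
        lead_snp = str(lead_of[anchor].lead_for(cpg_id)["snp_id"])
        for _, other in entries[1:]:
            tests.append(ColocTest(cpg_id, anchor, other, lead_snp))
    return tests


def run_coloc(
    summaries: list[TissueSummary],
    genotypes: GenotypeMatrix,
    genome_wide_cutoff: float,
    params: ColocParams | None = None,
) -> pd.DataFrame:
    """Run SMR for every selected test, BH-adjust jointly, then HEIDI.

    The LD reference for HEIDI is the supplied genotype matrix itself.
    Tests whose (CpG, lead SNP) pair is absent from the other tissue's
    summary get NaN statistics and a not-shared verdict.
    """
    params = params or ColocParams()
    by_tissue = {s.tissue: s for s in summaries}
    tests = select_coloc_tests(summaries, genome_wide_cutoff)
    rows = []
    for test in tests:
        anchor = by_tissue[test.anchor_tissue]
        other = by_tissue[test.other_tissue]
        stats_a = anchor.stats_for(test.cpg_id, test.lead_snp)
        stats_b = other.stats_for(test.cpg_id, test.lead_snp)
        row = {
            "cpg_id": test.cpg_id,
            "anchor_tissue": test.anchor_tissue,
            "other_tissue": test.other_tissue,
            "lead_snp": test.lead_snp,
            "smr_stat": np.nan,
            "smr_p": np.nan,
            "smr_fdr": np.nan,
            "heidi_stat": np.nan,
            "heidi_p": np.nan,
            "heidi_m": 0,
            "heidi_skipped": False,
        }
        if stats_a is not None and stats_b is not None:
            row["smr_stat"], row["smr_p"] = smr_test(
                stats_a["slope"], stats_a["se"], stats_b["slope"], stats_b["se"]
            )
        rows.append(row)
    results = pd.DataFrame(rows, columns=[c for c in COLOC_COLUMNS if c != "verdict"])
    if results.empty:
        results["verdict"] = pd.Series(dtype=object)
        return results
    computed = results["smr_p"].notna()
    adjusted = np.full(len(results), np.nan)
    if computed.any():
        adjusted[computed.to_numpy()] = bh_adjust(
            results.loc[computed, "smr_p"].to_numpy()
        )
    results["smr_fdr"] = adjusted

    for i in results.index[computed & (results["smr_fdr"] < params.smr_fdr_cutoff)]:
        anchor = by_tissue[results.at[i, "anchor_tissue"]]
        other = by_tissue[results.at[i, "other_tissue"]]
        cpg_id, lead_snp = results.at[i, "cpg_id"], results.at[i, "lead_snp"]
        cis_a = anchor.cis[anchor.cis["cpg_id"] == cpg_id]
        cis_b = other.cis[other.cis["cpg_id"] == cpg_id]
        merged = cis_a.merge(
            cis_b[["snp_id", "slope", "se"]], on="snp_id", suffixes=("_a", "_b")
        )
        merged = merged[merged["snp_id"].isin(genotypes.snp_ids)].reset_index(drop=True)
        if lead_snp not in set(merged["snp_id"]):
            results.at[i, "heidi_skipped"] = True
            continue
        ld = ld_matrix(genotypes, list(merged["snp_id"])).to_numpy()
        lead_index = int(merged.index[merged["snp_id"] == lead_snp][0])
        stat, p, m = heidi_test(
            merged["slope_a"].to_numpy(),
            merged["se_a"].to_numpy(),
            merged["slope_b"].to_numpy(),
            merged["se_b"].to_numpy(),
            ld,
            lead_index,
            params,
        )
        results.at[i, "heidi_stat"] = stat
        results.at[i, "heidi_p"] = p
        results.at[i, "heidi_m"] = m
        results.at[i, "heidi_skipped"] = m == 0

    results["verdict"] = [
        _pair_verdict(row, params) for _, row in results.iterrows()
    ]
    return results


def _pair_verdict(row: pd.Series, params: ColocParams) -> str:
    """shared iff SMR FDR significant and HEIDI finds no heterogeneity.

    When HEIDI was skipped for lack of instruments the verdict falls back
    to SMR alone (flagged via ``heidi_skipped``).
    """
    if not np.isfinite(row["smr_fdr"]) or row["smr_fdr"] >= params.smr_fdr_cutoff:
        return "not-shared"
    if row["heidi_skipped"] or not np.isfinite(row["heidi_p"]):
        return "shared"
    return "shared" if row["heidi_p"] > params.heidi_p_cutoff else "not-shared"


def classify_methqtls(
    coloc_results: pd.DataFrame,
    summaries: list[TissueSummary],
    genome_wide_cutoff: float,
    params: ColocParams | None = None,
) -> pd.DataFrame:
    """Label each tested (CpG, lead SNP) as common / shared / tissue-specific.

    shared: every pairwise comparison shared. common: shared, and the
    methQTL p-value is below the genome-wide cutoff in every tissue where
    the CpG is a tag. tissue-specific: shared in no comparison. CpGs shared
    in some but not all comparisons get the label ``partially-shared``.
    """
    params = params or ColocParams()
    by_tissue = {s.tissue: s for s in summaries}
    rows = []
    for (cpg_id, anchor, lead_snp), group in coloc_results.groupby(
        ["cpg_id", "anchor_tissue", "lead_snp"], sort=True
    ):
        verdicts = list(group["verdict"])
        n_shared = sum(v == "shared" for v in verdicts)
        if n_shared == len(verdicts):
            lead_ps = [
                float(s.lead_for(cpg_id)["p_value"])
                for s in summaries
                if s.lead_for(cpg_id) is not None
            ]
            if all(p < genome_wide_cutoff for p in lead_ps):
                label = "common"
            else:
                label = "shared"
        elif n_shared == 0:
            label = "tissue-specific"
        else:
            label = "partially-shared"
        rows.append(
            {
                "cpg_id": cpg_id,
                "anchor_tissue": anchor,
                "lead_snp": lead_snp,
                "n_comparisons": len(verdicts),
                "n_shared": n_shared,
                "label": label,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cpg_id",
            "anchor_tissue",
            "lead_snp",
            "n_comparisons",
            "n_shared",
            "label",
        ],
    )
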