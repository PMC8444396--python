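"""Simulation of genotype and methylation fixtures.

Everything is a pure function of (config, seed): HWE genotypes with chosen
allele frequencies, block-correlated beta values built from a shared
logit-normal latent level plus independent noise, injected cis effects
acting additively on the beta scale (with clipping), and multi-tissue
designs with shared / tissue-specific / linkage ground truth.

The within-block correlation target is met by a closed-form variance
ratio: for target r, the per-CpG noise variance is set to
var(latent) * (1 - r) / r, so that cor(cpg_i, cpg_j) = r in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from comethqtl.io_formats import GenotypeMatrix, MethylationMatrix


@dataclass
class BlockSpec:
    n_cpgs: int
    span_bp: int
    target_correlation: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_correlation < 1.0:
            raise ValueError("target correlation must be in [0, 1)")


@dataclass
class EffectSpec:
    """A cis effect injected into one block.

    ``snp_index`` of None means "use the SNP nearest the block center".
    ``kind``: shared (same causal SNP in every tissue), specific (effect in
    ``tissue_index`` only), linkage (tissue 0 driven by ``snp_index``, tissue
    1 by a distinct SNP in LD ``ld_r`` with it).
    """

    block_index: int
    snp_index: int | None
    slope: float
    kind: str = "shared"
    tissue_index: int = 0
    ld_r: float = 0.7


@dataclass
class SimConfig:
    n_samples: int = 200
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    chrom_length_bp: int = 20_000_000
    block_spec: list[BlockSpec] = field(default_factory=list)
    effects: list[EffectSpec] = field(default_factory=list)
    noise_sd: float = 0.05  # used when a block has no correlation target
    n_tissues: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")


def default_block_spec(
    n_blocks: int = 50, n_cpgs: int = 4, span_bp: int = 2000, target: float = 0.8
) -> list[BlockSpec]:
    return [BlockSpec(n_cpgs, span_bp, target) for _ in range(n_blocks)]


def _block_starts(config: SimConfig) -> list[int]:
    """Evenly spaced block start positions along the chromosome."""
    k = len(config.block_spec)
    step = config.chrom_length_bp // (k + 1)
    return [(i + 1) * step for i in range(k)]


def simulate_snp_panel(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """SNP positions (uniform without replacement, sorted) and allele
    frequencies (uniform in ``maf_range``); the panel shared by all cohorts."""
    if config.n_snps > config.chrom_length_bp:
        raise ValueError("more SNPs than base pairs")
    rng = rng or np.random.default_rng(config.seed)
    positions = np.sort(
        rng.choice(config.chrom_length_bp, size=config.n_snps, replace=False) + 1
    )
    freqs = rng.uniform(*config.maf_range, size=config.n_snps)
    return positions, freqs


def simulate_genotypes(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    sample_prefix: str = "s",
    panel: tuple[np.ndarray, np.ndarray] | None = None,
) -> GenotypeMatrix:
    """HWE genotypes: i.i.d. Binomial(2, p) dosages across samples on a
    fixed SNP panel (drawn from ``rng`` unless supplied)."""
    rng = rng or np.random.default_rng(config.seed)
    positions, freqs = panel if panel is not None else simulate_snp_panel(config, rng)
    dosage = rng.binomial(2, freqs[:, None], size=(config.n_snps, config.n_samples))
    width = len(str(config.n_snps))
    return GenotypeMatrix(
        snp_ids=[f"snp_{i + 1:0{width}d}" for i in range(config.n_snps)],
        chrom=np.array(["1"] * config.n_snps, dtype=object),
        pos=positions,
        ref_allele=np.array(["A"] * config.n_snps, dtype=object),
        alt_allele=np.array(["G"] * config.n_snps, dtype=object),
        dosage=dosage.astype(float),
        sample_ids=[f"{sample_prefix}{j + 1:04d}" for j in range(config.n_samples)],
    )


def nearest_snp_index(genotypes: GenotypeMatrix, pos: int) -> int:
    return int(np.argmin(np.abs(genotypes.pos - pos)))


def _resolve_effects(
    config: SimConfig, genotypes: GenotypeMatrix
) -> list[EffectSpec]:
    starts = _block_starts(config)
    resolved = []
    for eff in config.effects:
        snp_index = eff.snp_index
        if snp_index is None:
            spec = config.block_spec[eff.block_index]
            center = starts[eff.block_index] + spec.span_bp // 2
            snp_index = nearest_snp_index(genotypes, center)
        resolved.append(
            EffectSpec(
                eff.block_index, snp_index, eff.slope, eff.kind,
                eff.tissue_index, eff.ld_r,
            )
        )
    return resolved


def simulate_methylation(
    config: SimConfig,
    genotypes: GenotypeMatrix,
    rng: np.random.Generator | None = None,
    effect_dosage: dict[int, np.ndarray] | None = None,
) -> MethylationMatrix:
    """Block-correlated beta values with injected cis effects.

    Per block a latent logit-normal level is drawn per sample; every member
    CpG observes latent + effect + independent Gaussian noise, clipped to
    [0, 1]. ``effect_dosage`` overrides the dosage vector used for specific
    effects (multi-tissue designs); by default each effect uses the dosage
    of its resolved SNP in ``genotypes``.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    starts = _block_starts(config)
    effects = _resolve_effects(config, genotypes)
    cpg_ids, chroms, positions, rows = [], [], [], []
    for b, spec in enumerate(config.block_spec):
        mu = rng.uniform(-1.0, 1.0)
        latent = expit(mu + 0.5 * rng.standard_normal(config.n_samples))
        for k, eff in enumerate(effects):
            if eff.block_index != b:
                continue
            dosage = (
                effect_dosage[k]
                if effect_dosage is not None and k in effect_dosage
                else genotypes.dosage[eff.snp_index]
            )
            latent = latent + eff.slope * dosage
        var_latent = float(np.var(latent))
        if spec.target_correlation > 0 and var_latent > 0:
            noise_sd = np.sqrt(
                var_latent * (1.0 - spec.target_correlation) / spec.target_correlation
            )
        else:
            noise_sd = config.noise_sd
        if spec.n_cpgs == 1:
            offsets = [spec.span_bp // 2]
        else:
            offsets = np.linspace(0, spec.span_bp, spec.n_cpgs).astype(int)
        for j in range(spec.n_cpgs):
            # deterministic per-CpG baseline offset: separates the per-CpG
            # medians so the medoid tag is stable across cohorts/tissues,
            # without affecting within-block correlations
            offset = 0.03 * (j - (spec.n_cpgs - 1) / 2.0)
            noise = noise_sd * rng.standard_normal(config.n_samples)
            rows.append(np.clip(latent + offset + noise, 0.0, 1.0))
            cpg_ids.append(f"cg_b{b + 1:03d}_{j + 1:02d}")
            chroms.append("1")
            positions.append(starts[b] + int(offsets[j]))
    return MethylationMatrix(
        cpg_ids=cpg_ids,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        beta=np.array(rows, dtype=float),
        sample_ids=list(genotypes.sample_ids),
    )


def simulate_correlated_snp(
    dosage: np.ndarray, maf: float, r: float, rng: np.random.Generator
) -> np.ndarray:
    """A SNP in LD ``r`` with an existing one, via haplotype copying.

    Each of the two allele copies of the new SNP equals the corresponding
    copy of the template with probability r and is an independent
    Bernoulli(maf) draw otherwise; the allele correlation is then r when
    both SNPs share the frequency ``maf``.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("LD r must be in [0, 1]")
    n = dosage.size
    # split dosage into two haplotype copies (order is exchangeable)
    h1 = (dosage >= 1).astype(float)
    h2 = (dosage >= 2).astype(float)
    out = np.zeros(n)
    for h in (h1, h2):
        copy = rng.random(n) < r
        fresh = (rng.random(n) < maf).astype(float)
        out += np.where(copy, h, fresh)
    return out


def simulate_multitissue(
    config: SimConfig,
) -> tuple[list[tuple[MethylationMatrix, GenotypeMatrix]], pd.DataFrame]:
    """Per-tissue (methylation, genotypes) with a ground-truth effect table.

    Tissues have disjoint sample sets but share the SNP panel (ids,
    positions, frequencies). Shared effects use the same causal SNP in all
    tissues; specific effects act in one tissue only; linkage effects drive
    tissue 0 from the designated SNP and tissue 1 from a distinct SNP in
    LD ``ld_r`` with it.
    """
    if config.n_tissues < 2:
        raise ValueError("simulate_multitissue needs n_tissues >= 2")
    master = np.random.default_rng(config.seed)
    panel = simulate_snp_panel(config, np.random.default_rng(config.seed))
    positions, freqs = panel
    template = simulate_genotypes(
        config, np.random.default_rng(config.seed + 1), sample_prefix="tmpl_s",
        panel=panel,
    )
    effects = _resolve_effects(config, template)

    linkage_partner: dict[int, int] = {}
    for k, eff in enumerate(effects):
        if eff.kind == "linkage":
            # partner is the nearest other SNP; its dosage is rewritten in LD
            order = np.argsort(np.abs(template.pos - template.pos[eff.snp_index]))
            linkage_partner[k] = int(order[1])

    tissues = []
    for t in range(config.n_tissues):
        rng = np.random.default_rng(master.integers(2**63))
        geno = simulate_genotypes(config, rng, sample_prefix=f"t{t}_s", panel=panel)
        for k, partner in linkage_partner.items():
            causal = effects[k].snp_index
            geno.dosage[partner] = simulate_correlated_snp(
                geno.dosage[causal], float(freqs[partner]), effects[k].ld_r, rng
            )
        effect_dosage = {}
        for k, eff in enumerate(effects):
            if eff.kind == "specific" and t != eff.tissue_index:
                effect_dosage[k] = np.zeros(config.n_samples)
            elif eff.kind == "linkage":
                source = eff.snp_index if t == 0 else linkage_partner[k]
                effect_dosage[k] = geno.dosage[source]
        meth = simulate_methylation(config, geno, rng, effect_dosage=effect_dosage)
        tissues.append((meth, geno))

    truth_rows = []
    for k, eff in enumerate(effects):
        truth_rows.append(
            {
                "effect_index": k,
                "block_index": eff.block_index,
                "snp_id": template.snp_ids[eff.snp_index],
                "partner_snp_id": (
                    template.snp_ids[linkage_partner[k]]
                    if k in linkage_partner
                    else ""
                ),
                "slope": eff.slope,
                "kind": eff.kind,
                "tissue_index": eff.tissue_index,
                "true_class": "shared" if eff.kind == "shared" else "tissue-specific",
            }
        )
    return tissues, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# compact two-cohort region simulator for SMR/HEIDI calibration studies


def simulate_region_pair(
    n_samples: int,
    n_proxies: int,
    maf: float,
    effect_a: float,
    effect_b: float,
    mode: str,
    rng: np.random.Generator,
    noise_sd: float = 0.05,
    ld_range: tuple[float, float] = (0.5, 0.85),
    linkage_ld: float = 0.7,
) -> dict:
    """Two independent cohorts sharing one LD region; one trait per cohort.

    ``pleiotropy``: a single causal SNP (index 0) drives the trait in both
    cohorts; the other SNPs are pure LD proxies. ``linkage``: cohort A is
    driven by SNP 0 and cohort B by SNP 1, where SNP 1 is a distinct variant
    in LD ``linkage_ld`` with SNP 0. Returns dosage matrices, traits, and
    the proxies' LD profile.
    """
    if mode not in ("pleiotropy", "linkage"):
        raise ValueError(f"unknown mode {mode!r}")
    ld_profile = rng.uniform(*ld_range, size=n_proxies)

    def cohort(rng_c: np.random.Generator) -> np.ndarray:
        causal = rng_c.binomial(2, maf, size=n_samples).astype(float)
        cols = [causal]
        if mode == "linkage":
            cols.append(simulate_correlated_snp(causal, maf, linkage_ld, rng_c))
        for r in ld_profile:
            cols.append(simulate_correlated_snp(causal, maf, r, rng_c))
        return np.array(cols)

    dos_a = cohort(rng)
    dos_b = cohort(rng)
    causal_b = 0 if mode == "pleiotropy" else 1
    trait_a = 0.4 + effect_a * dos_a[0] + noise_sd * rng.standard_normal(n_samples)
    trait_b = (
        0.4 + effect_b * dos_b[causal_b] + noise_sd * rng.standard_normal(n_samples)
    )
    return {
        "dosage_a": dos_a,
        "dosage_b": dos_b,
        "trait_a": np.clip(trait_a, 0, 1),
        "trait_b": np.clip(trait_b, 0, 1),
        "causal_a": 0,
        "causal_b": causal_b,
        "ld_profile": ld_profile,
    }
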