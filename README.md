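# comethqtl

Cis methQTL mapping on CpG correlation blocks, with cross-tissue
classification of methQTLs by SMR + HEIDI colocalization.

The pipeline follows a two-phase design:

1. **Correlation-block calling** — CpGs with correlated methylation levels
   are grouped per chromosome by building a similarity graph (Pearson
   correlation, thresholded at 0.2, weighted by a Gaussian of the genomic
   distance with sd 3 kb, zeroed beyond 500 kb) and running Louvain
   community detection. Each block is represented by its medoid tag-CpG.
2. **Cis association testing** — every tag-CpG is regressed on the dosage
   of each SNP closer than 500 kb (OLS with optional covariates), with a
   Bonferroni-style genome-wide cutoff of
   `alpha / (total blocks x mean cis SNPs per tag-CpG)` and per-CpG
   lead-SNP selection.

On top of that, per-tissue summary statistics can be compared pairwise
across tissues: the SMR test asks whether two tissues share an association
at the anchor tissue's lead SNP (BH-adjusted jointly over all tests), and
the HEIDI heterogeneity test separates pleiotropy from linkage using LD
from the study genotypes. Tested CpGs are labeled **common** (shared in
every comparison and genome-wide significant in every tissue), **shared**
(shared in every comparison), **tissue-specific** (shared in none), or
**partially-shared**.

Supporting modules: genotype QC (Hardy–Weinberg exact test, missingness,
MAF, sample missingness), annotation-overlap enrichment (one-sided Fisher
tests, promoter regions as TSS −1.5 kb/+0.5 kb), and a synthetic-data
generator (HWE genotypes, block-correlated beta values, injected cis
effects, multi-tissue shared/specific/linkage designs) so everything is
testable without external data.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: exact cutoff
arithmetic, oracle equivalence of the core statistics (HWE exact test vs
full enumeration, OLS vs normal equations, Fisher vs hypergeometric
summation, BH vs step-up), null calibration, planted-partition block
recovery (ARI ≥ 0.9), slope parameter recovery, pleiotropy/linkage
classification recovery, and byte-identical rerun determinism.

## CLI

```bash
comethqtl simulate --seed 1 --n-samples 100 --n-snps 500 --n-blocks 10 --out-dir sim/
comethqtl qc --genotypes sim/genotypes.tsv --out qc.tsv --report qc.json
comethqtl blocks --methylation sim/methylation.tsv --seed 1 \
    --out-bed blocks.bed --out-members members.tsv
comethqtl call --methylation sim/methylation.tsv --genotypes qc.tsv \
    --members members.tsv --out-prefix qtl
comethqtl coloc --summaries t0=qtl0.full.tsv,t1=qtl1.full.tsv \
    --genotypes qc.tsv --cutoff 1e-8 --out coloc.tsv
comethqtl classify --coloc-results coloc.tsv \
    --summaries t0=qtl0.full.tsv,t1=qtl1.full.tsv --cutoff 1e-8 --out classes.tsv
comethqtl enrich --query lead.tsv --background full.tsv \
    --annotations promoters.bed --out enrichment.tsv
comethqtl run --config config.yaml          # full pipeline + JSON manifest
```

Genotypes are read from VCF (GT field; 0/0 → 0, 0/1 → 1, 1/1 → 2,
./. → missing, phased treated as unphased, multi-allelic records skipped)
or a plain dosage TSV. Methylation comes as a `cpg_id/chrom/pos/<samples>`
TSV or a BED-like table. Coordinates are 1-based inclusive internally and
chromosome names are normalized by stripping a leading `chr`.

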