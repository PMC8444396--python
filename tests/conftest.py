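import numpy as np
import pytest

from comethqtl.io_formats import GenotypeMatrix, MethylationMatrix


@pytest.fixture
def small_methylation() -> MethylationMatrix:
    return MethylationMatrix(
        cpg_ids=["cg1", "cg2", "cg3"],
        chrom=np.array(["1", "1", "2"], dtype=object),
        pos=np.array([100, 250, 90]),
        beta=np.array([[0.1, 0.2], [0.9, 0.8], [0.5, np.nan]]),
        sample_ids=["sA", "sB"],
    )


@pytest.fixture
def small_genotypes() -> GenotypeMatrix:
    rng = np.random.default_rng(0)
    n_snps, n_samples = 8, 10
    dosage = rng.binomial(2, 0.3, size=(n_snps, n_samples)).astype(float)
    return GenotypeMatrix(
        snp_ids=[f"rs{i}" for i in range(n_snps)],
        chrom=np.array(["1"] * n_snps, dtype=object),
        pos=np.arange(1000, 1000 + n_snps * 50, 50),
        ref_allele=np.array(["A"] * n_snps, dtype=object),
        alt_allele=np.array(["G"] * n_snps, dtype=object),
        dosage=dosage,
        sample_ids=[f"s{j}" for j in range(n_samples)],
    )


@pytest.fixture
def methylation_tsv(tmp_path, small_methylation):
    from comethqtl.io_formats import write_methylation

    path = tmp_path / "meth.tsv"
    write_methylation(small_methylation, path)
    return path
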