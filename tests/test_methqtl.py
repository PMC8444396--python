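import numpy as np
import pandas as pd
import pytest
from scipy import stats

from comethqtl.correlation_blocks import CorrelationBlock
from comethqtl.io_formats import CovariateTable, GenotypeMatrix, MethylationMatrix
from comethqtl.methqtl import (
    AssocParams,
    AssociationSkipped,
    call_methqtls,
    cis_candidates,
    fit_association,
    genome_wide_cutoff,
    replication_cutoff,
    select_lead_snps,
    select_tag_cpg,
)


def ols_oracle(y, X):
    """Closed-form normal equations with residual-based standard errors,
    independent of statsmodels."""
    X = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    return beta[1], se[1], p[1]


def meth_from_rows(rows, positions=None, chrom="1"):
    rows = np.asarray(rows, dtype=float)
    n = rows.shape[0]
    return MethylationMatrix(
        cpg_ids=[f"cg{i}" for i in range(n)],
        chrom=np.array([chrom] * n, dtype=object),
        pos=np.asarray(positions if positions is not None else np.arange(n) * 100 + 1),
        beta=rows,
        sample_ids=[f"s{j}" for j in range(rows.shape[1])],
    )


class TestSelectTagCpG:
    def test_singleton(self):
        matrix = meth_from_rows([[0.5, 0.6]])
        block = CorrelationBlock("1", ["cg0"])
        assert select_tag_cpg(block, matrix) == "cg0"

    def test_middle_of_three(self):
        matrix = meth_from_rows(
            [[0.2, 0.2], [0.5, 0.5], [0.9, 0.9]]
        )
        block = CorrelationBlock("1", ["cg0", "cg1", "cg2"])
        assert select_tag_cpg(block, matrix) == "cg1"

    def test_even_block_lower_median(self):
        # per-CpG medians 0.1, 0.4, 0.6, 0.9 -> lower-central value is 0.4
        matrix = meth_from_rows(
            [[0.1, 0.1], [0.4, 0.4], [0.6, 0.6], [0.9, 0.9]]
        )
        block = CorrelationBlock("1", [f"cg{i}" for i in range(4)])
        assert select_tag_cpg(block, matrix) == "cg1"

    def test_tie_broken_by_position(self):
        matrix = meth_from_rows(
            [[0.5, 0.5], [0.5, 0.5], [0.5, 0.5]], positions=[300, 100, 200]
        )
        # after load, rows re-sorted: cg1 (100), cg2 (200), cg0 (300)
        block = CorrelationBlock("1", ["cg0", "cg1", "cg2"])
        assert select_tag_cpg(block, matrix) == "cg1"

    def test_all_missing_cpg_excluded(self):
        matrix = meth_from_rows(
            [[np.nan, np.nan], [0.5, 0.5], [0.2, 0.2], [0.9, 0.9]]
        )
        block = CorrelationBlock("1", [f"cg{i}" for i in range(4)])
        assert select_tag_cpg(block, matrix) == "cg1"


class TestCisCandidates:
    def make_geno(self, positions, chrom="1"):
        n = len(positions)
        return GenotypeMatrix(
            snp_ids=[f"rs{i}" for i in range(n)],
            chrom=np.array([chrom] * n, dtype=object),
            pos=np.asarray(positions),
            ref_allele=np.array(["A"] * n, dtype=object),
            alt_allele=np.array(["G"] * n, dtype=object),
            dosage=np.zeros((n, 2)),
            sample_ids=["s0", "s1"],
        )

    def test_boundary_strictly_less(self):
        geno = self.make_geno([1_499_999, 1_500_000])
        found = cis_candidates(1_000_000, "1", geno, 500_000)
        assert found == ["rs0"]  # 499,999 in; 500,000 out

    def test_other_chromosome_excluded(self):
        geno = self.make_geno([1_000_000], chrom="2")
        assert cis_candidates(1_000_000, "1", geno, 500_000) == []

    def test_symmetric_window(self):
        geno = self.make_geno([600_000, 1_400_001])
        found = cis_candidates(1_000_000, "1", geno, 500_000)
        assert found == ["rs0", "rs1"]


class TestFitAssociation:
    def test_perfect_linear_fit(self):
        g = np.array([0.0, 1.0, 2.0] * 10)
        y = 0.2 + 0.15 * g
        slope, se, p, n = fit_association(y, g)
        assert slope == pytest.approx(0.15, abs=1e-10)
        assert p < 1e-200
        assert n == 30

    def test_joint_permutation_invariance(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.3, 50).astype(float)
        y = 0.4 + 0.1 * g + rng.normal(0, 0.05, 50)
        base = fit_association(y, g)
        perm = rng.permutation(50)
        permuted = fit_association(y[perm], g[perm])
        assert base[:3] == pytest.approx(permuted[:3], rel=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = 60
            g = rng.binomial(2, 0.4, n).astype(float)
            cov = rng.normal(size=(n, 2))
            y = 0.3 + 0.08 * g + cov @ [0.02, -0.05] + rng.normal(0, 0.04, n)
            slope, se, p, _ = fit_association(
                y, g, pd.DataFrame(cov, columns=["c1", "c2"])
            )
            o_slope, o_se, o_p = ols_oracle(y, np.column_stack([g, cov]))
            assert slope == pytest.approx(o_slope, abs=1e-10)
            assert se == pytest.approx(o_se, abs=1e-10)
            assert p == pytest.approx(o_p, rel=1e-8)

    def test_categorical_covariate_oracle(self):
        rng = np.random.default_rng(2)
        n = 80
        g = rng.binomial(2, 0.3, n).astype(float)
        sex = rng.choice(["m", "f"], n)
        y = 0.4 + 0.1 * g + 0.05 * (sex == "m") + rng.normal(0, 0.05, n)
        table = CovariateTable(
            pd.DataFrame({"sex": sex}, index=[f"s{j}" for j in range(n)])
        )
        design = table.design_columns(["sex"])
        slope, se, p, _ = fit_association(y, g, design)
        o_slope, o_se, o_p = ols_oracle(
            y, np.column_stack([g, design.to_numpy()])
        )
        assert slope == pytest.approx(o_slope, abs=1e-10)
        assert se == pytest.approx(o_se, abs=1e-10)

    def test_allele_flip_negates_slope(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.3, 100).astype(float)
        y = 0.4 + 0.1 * g + rng.normal(0, 0.05, 100)
        slope, se, p, _ = fit_association(y, g)
        fslope, fse, fp, _ = fit_association(y, 2.0 - g)
        assert fslope == pytest.approx(-slope, rel=1e-12)
        assert fse == pytest.approx(se, rel=1e-12)
        assert fp == pytest.approx(p, rel=1e-12)

    def test_monomorphic_skipped(self):
        with pytest.raises(AssociationSkipped, match="monomorphic"):
            fit_association(np.linspace(0.1, 0.9, 20), np.ones(20))

    def test_rank_deficient_skipped(self):
        g = np.array([0.0, 1.0, 2.0] * 10)
        cov = pd.DataFrame({"dup": g})  # duplicates the dosage column
        with pytest.raises(AssociationSkipped, match="rank-deficient"):
            fit_association(np.linspace(0.1, 0.9, 30), g, cov)

    def test_too_few_complete_cases(self):
        y = np.array([0.1, 0.2, np.nan, np.nan, np.nan])
        g = np.array([0.0, 1.0, 2.0, 0.0, 1.0])
        with pytest.raises(AssociationSkipped, match="insufficient"):
            fit_association(y, g)

    def test_complete_case_removal(self):
        rng = np.random.default_rng(4)
        g = rng.binomial(2, 0.4, 60).astype(float)
        y = 0.4 + 0.1 * g + rng.normal(0, 0.05, 60)
        y_missing = y.copy()
        y_missing[:10] = np.nan
        slope, se, p, n = fit_association(y_missing, g)
        assert n == 50
        expected = fit_association(y[10:], g[10:])
        assert slope == pytest.approx(expected[0], rel=1e-12)


def build_inputs(n_samples=200, seed=0, slope=0.1, noise=0.05):
    rng = np.random.default_rng(seed)
    sample_ids = [f"s{j}" for j in range(n_samples)]
    dosage = rng.binomial(2, 0.3, size=(3, n_samples)).astype(float)
    geno = GenotypeMatrix(
        snp_ids=["rs0", "rs1", "rs2"],
        chrom=np.array(["1"] * 3, dtype=object),
        pos=np.array([90_000, 100_000, 110_000]),
        ref_allele=np.array(["A"] * 3, dtype=object),
        alt_allele=np.array(["G"] * 3, dtype=object),
        dosage=dosage,
        sample_ids=sample_ids,
    )
    y = np.clip(0.3 + slope * dosage[1] + rng.normal(0, noise, n_samples), 0, 1)
    meth = MethylationMatrix(
        cpg_ids=["cg0"],
        chrom=np.array(["1"], dtype=object),
        pos=np.array([100_500]),
        beta=y[None, :],
        sample_ids=sample_ids,
    )
    return meth, geno


class TestCallMethQTLs:
    def test_one_block_three_cis_snps(self):
        meth, geno = build_inputs()
        blocks = [CorrelationBlock("1", ["cg0"], tag_cpg_id="cg0")]
        records = call_methqtls(meth, geno, None, blocks)
        assert len(records) == 3
        assert set(records["snp_id"]) == {"rs0", "rs1", "rs2"}
        assert (records["distance"] == records["snp_pos"] - records["cpg_pos"]).all()

    def test_slope_recovery_within_3se(self):
        meth, geno = build_inputs(seed=5, slope=0.1)
        blocks = [CorrelationBlock("1", ["cg0"], tag_cpg_id="cg0")]
        records = call_methqtls(meth, geno, None, blocks)
        causal = records[records["snp_id"] == "rs1"].iloc[0]
        assert abs(causal["slope"] - 0.1) < 3 * causal["se"]

    def test_no_cis_snps_empty_with_warning(self, caplog):
        import logging

        meth, geno = build_inputs()
        geno.pos = geno.pos + 10_000_000  # move SNPs out of the window
        blocks = [CorrelationBlock("1", ["cg0"], tag_cpg_id="cg0")]
        with caplog.at_level(logging.WARNING):
            records = call_methqtls(meth, geno, None, blocks)
        assert records.empty
        assert any("no cis SNPs" in m for m in caplog.messages)

    def test_no_overlapping_samples_error(self):
        meth, geno = build_inputs()
        meth.sample_ids = [f"x{j}" for j in range(meth.n_samples)]
        blocks = [CorrelationBlock("1", ["cg0"], tag_cpg_id="cg0")]
        with pytest.raises(ValueError, match="overlapping"):
            call_methqtls(meth, geno, None, blocks)


class TestCutoffs:
    def test_genome_wide_cutoff_paper_counts(self):
        cutoff = genome_wide_cutoff([82_271, 69_219, 75_779, 76_109], 1905, 0.05)
        assert cutoff == pytest.approx(8.65e-11, rel=5e-3)

    def test_single_block_single_snp(self):
        assert genome_wide_cutoff([1], 1, 0.05) == 0.05

    def test_doubling_counts_halves_cutoff(self):
        counts = [100, 200, 300]
        assert genome_wide_cutoff(
            [2 * c for c in counts], 10, 0.05
        ) == pytest.approx(genome_wide_cutoff(counts, 10, 0.05) / 2)

    def test_zero_denominator_error(self):
        with pytest.raises(ValueError):
            genome_wide_cutoff([0], 0, 0.05)

    def test_replication_cutoff_paper_counts(self):
        cutoff = replication_cutoff([2508, 696, 1010, 868], 0.05)
        assert cutoff == pytest.approx(9.84e-6, rel=5e-3)

    def test_replication_single(self):
        assert replication_cutoff([1], 0.05) == 0.05

    def test_replication_algebra(self):
        counts = [17, 23, 41]
        assert replication_cutoff(counts, 0.05) * sum(counts) == pytest.approx(0.05)


class TestSelectLeadSnps:
    def frame(self, rows):
        return pd.DataFrame(
            rows,
            columns=["cpg_id", "snp_id", "p_value", "distance"],
        )

    def test_lowest_p_wins(self):
        records = self.frame(
            [["cg1", "rsA", 1e-8, 100], ["cg1", "rsB", 1e-12, 200]]
        )
        lead = select_lead_snps(records)
        assert list(lead["snp_id"]) == ["rsB"]

    def test_tie_broken_by_distance(self):
        records = self.frame(
            [["cg1", "rsA", 1e-10, 5000], ["cg1", "rsB", 1e-10, 100]]
        )
        lead = select_lead_snps(records)
        assert list(lead["snp_id"]) == ["rsB"]

    def test_tie_broken_by_snp_id(self):
        records = self.frame(
            [["cg1", "rsB", 1e-10, 100], ["cg1", "rsA", 1e-10, -100]]
        )
        lead = select_lead_snps(records)
        assert list(lead["snp_id"]) == ["rsA"]

    def test_one_row_per_cpg(self):
        rng = np.random.default_rng(0)
        rows = [
            [f"cg{i % 5}", f"rs{j}", rng.uniform(), int(rng.integers(-5000, 5000))]
            for j, i in enumerate(rng.integers(0, 5, 40))
        ]
        lead = select_lead_snps(self.frame(rows))
        assert lead["cpg_id"].is_unique
        assert set(lead["cpg_id"]) == {f"cg{i}" for i in range(5)}


class TestCalibrationAndBias:
    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(42)
        n, n_tests = 100, 500
        pvals = []
        for _ in range(n_tests):
            g = rng.binomial(2, 0.3, n).astype(float)
            y = np.clip(rng.normal(0.5, 0.1, n), 0, 1)
            pvals.append(fit_association(y, g)[2])
        frac = np.mean(np.array(pvals) <= 0.05)
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / n_tests)
        assert abs(frac - 0.05) <= half_width

    def test_mean_signed_bias_small(self):
        rng = np.random.default_rng(7)
        n = 200
        slopes = rng.choice([-0.2, -0.1, -0.05, 0.05, 0.1, 0.2], size=200)
        errors = []
        for true_slope in slopes:
            g = rng.binomial(2, 0.3, n).astype(float)
            y = 0.5 + true_slope * g + rng.normal(0, 0.05, n)
            slope, se, _, _ = fit_association(y, g)
            errors.append(slope - true_slope)
            assert abs(slope - true_slope) < 3 * se
        assert abs(np.mean(errors)) < 0.01
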