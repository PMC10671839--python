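import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from prgscreen import CohortPair, ExpressionMatrix
from prgscreen.diffexpr import (
    VariancePrior,
    de_table_for_cohorts,
    fit_variance_prior,
    gene_pooled_stats,
    moderated_t_table,
    paired_t_test,
)
from conftest import random_matrix


def make_matrix(vals, genes=None):
    vals = np.atleast_2d(np.asarray(vals, float))
    genes = genes or [f"G{i}" for i in range(vals.shape[0])]
    cols = [f"S{j}" for j in range(vals.shape[1])]
    return ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=cols)), cols


class TestPooledStats:
    def test_hand_arithmetic_zero_variance(self):
        m, cols = make_matrix([[2, 2, 4, 4]])
        pair = CohortPair("c", (cols[0], cols[1]), (cols[2], cols[3]))
        ps = gene_pooled_stats(m, pair)
        assert ps.log2fc[0] == 2.0
        assert ps.s_sq[0] == 0.0

    def test_hand_pooled_variance(self):
        # resistant {5,7}, sensitive {1,3}: lfc 4, pooled s^2 = (2+2)/2 = 2
        m, cols = make_matrix([[1, 3, 5, 7]])
        pair = CohortPair("c", (cols[0], cols[1]), (cols[2], cols[3]))
        ps = gene_pooled_stats(m, pair)
        assert ps.log2fc[0] == 4.0
        assert ps.s_sq[0] == 2.0
        assert ps.d_g == 2.0
        assert ps.v_g == 1.0

    def test_sample_order_invariance(self, rng):
        m = random_matrix(rng, 10, 6)
        a = gene_pooled_stats(m, CohortPair("c", ("S0", "S1", "S2"), ("S3", "S4", "S5")))
        b = gene_pooled_stats(m, CohortPair("c", ("S2", "S0", "S1"), ("S5", "S3", "S4")))
        np.testing.assert_allclose(a.log2fc, b.log2fc, atol=1e-12)
        np.testing.assert_allclose(a.s_sq, b.s_sq, atol=1e-12)

    def test_arm_exchange_negates_log2fc(self, rng, two_arm_pair):
        m = random_matrix(rng, 10, 6)
        fwd = gene_pooled_stats(m, two_arm_pair)
        rev = gene_pooled_stats(
            m, CohortPair("c1", two_arm_pair.resistant_samples, two_arm_pair.sensitive_samples)
        )
        np.testing.assert_allclose(fwd.log2fc, -rev.log2fc, atol=1e-12)

    def test_singleton_arms_flagged_undefined(self):
        m, cols = make_matrix([[1, 2]])
        ps = gene_pooled_stats(m, CohortPair("c", (cols[0],), (cols[1],)))
        assert np.isnan(ps.s_sq[0])
        assert ps.d_g == 0.0


class TestVariancePrior:
    def test_all_equal_degenerate_limit(self):
        prior = fit_variance_prior(np.full(50, 1.7), d_g=4.0)
        assert np.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(1.7)

    def test_below_sampling_noise_clamps_to_infinite_d0(self, rng):
        # spread of log s^2 far below trigamma(d_g/2) sampling noise
        s_sq = np.exp(rng.normal(0, 0.01, 200))
        prior = fit_variance_prior(s_sq, d_g=2.0)
        assert np.isinf(prior.d0)

    def test_parameter_recovery_from_scaled_chisquare(self):
        # s^2 ~ s0^2 * (chi2_dg/dg) / (chi2_d0/d0) with d0=4, s0^2=2
        rng = np.random.default_rng(2024)
        d0, s0_sq, d_g, n = 4.0, 2.0, 4.0, 5000
        sigma_sq = s0_sq * d0 / rng.chisquare(d0, n)
        s_sq = sigma_sq * rng.chisquare(d_g, n) / d_g
        prior = fit_variance_prior(s_sq, d_g)
        assert prior.d0 == pytest.approx(d0, rel=0.25)
        assert prior.s0_sq == pytest.approx(s0_sq, rel=0.10)


class TestModeratedT:
    def test_d0_zero_equals_ordinary_pooled_t(self, rng, two_arm_pair):
        m = random_matrix(rng, 30, 6)
        tab = moderated_t_table(m, two_arm_pair, VariancePrior(d0=0.0, s0_sq=1.0))
        ps = gene_pooled_stats(m, two_arm_pair)
        expected_t = ps.log2fc / np.sqrt(ps.s_sq * ps.v_g)
        np.testing.assert_allclose(tab["t"], expected_t, rtol=1e-10)
        # and it matches scipy's two-sample equal-variance t
        res = m.data[list(two_arm_pair.resistant_samples)].to_numpy()
        sen = m.data[list(two_arm_pair.sensitive_samples)].to_numpy()
        sp = stats.ttest_ind(res.T, sen.T, equal_var=True)
        np.testing.assert_allclose(tab["t"], sp.statistic, rtol=1e-10)
        np.testing.assert_allclose(tab["p"], sp.pvalue, rtol=1e-8)

    def test_infinite_d0_full_shrinkage_normal_p(self, rng, two_arm_pair):
        m = random_matrix(rng, 20, 6)
        prior = VariancePrior(d0=np.inf, s0_sq=2.5)
        tab = moderated_t_table(m, two_arm_pair, prior)
        ps = gene_pooled_stats(m, two_arm_pair)
        np.testing.assert_allclose(
            tab["t"], ps.log2fc / np.sqrt(2.5 * ps.v_g), rtol=1e-12
        )
        np.testing.assert_allclose(
            tab["p"], 2 * stats.norm.sf(np.abs(tab["t"])), rtol=1e-12
        )

    def test_matches_independent_formula_reimplementation(self, two_arm_pair):
        """Straight-line oracle: recompute every quantity from raw arrays."""
        rng = np.random.default_rng(77)
        sigma2 = 1.5 * 5 / rng.chisquare(5, 200)  # heteroscedastic genes
        vals = 8 + rng.normal(0, 1, (200, 6)) * np.sqrt(sigma2)[:, None]
        m = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"G{i}" for i in range(200)],
                         columns=[f"S{j}" for j in range(6)])
        )
        res = m.data[list(two_arm_pair.resistant_samples)].to_numpy()
        sen = m.data[list(two_arm_pair.sensitive_samples)].to_numpy()
        n1 = n2 = 3
        lfc = res.mean(1) - sen.mean(1)
        s_sq = (res.var(1, ddof=1) * (n1 - 1) + sen.var(1, ddof=1) * (n2 - 1)) / (n1 + n2 - 2)
        d_g = n1 + n2 - 2
        e = np.log(s_sq)
        evar = np.var(e, ddof=1) - special.polygamma(1, d_g / 2)
        # invert trigamma by bisection (independent of the package's Newton)
        lo, hi = 1e-6, 1e8
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if special.polygamma(1, mid) > evar:
                lo = mid
            else:
                hi = mid
        d0 = 2 * lo
        s0 = np.exp(
            e.mean()
            - special.digamma(d_g / 2) + np.log(d_g / 2)
            + special.digamma(d0 / 2) - np.log(d0 / 2)
        )
        s_tilde = (d0 * s0 + d_g * s_sq) / (d0 + d_g)
        t_oracle = lfc / np.sqrt(s_tilde * (1 / n1 + 1 / n2))
        p_oracle = 2 * stats.t.sf(np.abs(t_oracle), d0 + d_g)

        prior = fit_variance_prior(s_sq, d_g)
        tab = moderated_t_table(m, two_arm_pair, prior)
        np.testing.assert_allclose(tab["t"], t_oracle, atol=1e-10, rtol=1e-10)
        np.testing.assert_allclose(tab["p"], p_oracle, atol=1e-10)

    def test_monotone_shrinkage_in_d0(self, rng, two_arm_pair):
        m = random_matrix(rng, 15, 6)
        ps = gene_pooled_stats(m, two_arm_pair)
        ordinary = ps.log2fc / np.sqrt(ps.s_sq * ps.v_g)
        prev_gap = None
        for d0 in [10.0, 1.0, 0.1, 0.01]:
            tab = moderated_t_table(m, two_arm_pair, VariancePrior(d0, 2.0))
            gap = np.max(np.abs(tab["t"].to_numpy() - ordinary))
            if prev_gap is not None:
                assert gap <= prev_gap + 1e-12
            prev_gap = gap
        assert prev_gap < 1e-2 * np.max(np.abs(ordinary))

    def test_matches_limma_ebayes(self, tmp_path):
        """Cross-check against the Bioconductor reference implementation."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; limma oracle cannot run")
        rng = np.random.default_rng(7)
        n_genes, n1, n2 = 120, 4, 3
        sigma2 = 2.0 * 4 / rng.chisquare(4, n_genes)
        vals = rng.normal(0, 1, (n_genes, n1 + n2)) * np.sqrt(sigma2)[:, None] + 8
        genes = [f"G{i}" for i in range(n_genes)]
        cols = [f"r{i}" for i in range(n1)] + [f"s{i}" for i in range(n2)]
        df = pd.DataFrame(vals, index=genes, columns=cols)
        df.to_csv(tmp_path / "m.tsv", sep="\t")
        rscript = f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("{tmp_path / 'm.tsv'}", row.names=1))
        design <- cbind(Intercept=1, res=c(rep(1,{n1}), rep(0,{n2})))
        fit <- eBayes(lmFit(x, design))
        out <- data.frame(gene=rownames(x), t=fit$t[,"res"], p=fit$p.value[,"res"])
        write.table(out, "{tmp_path / 'limma.tsv'}", sep="\\t", row.names=FALSE, quote=FALSE)
        """
        subprocess.run(["Rscript", "-e", rscript], check=True, capture_output=True)
        limma = pd.read_csv(tmp_path / "limma.tsv", sep="\t").set_index("gene")

        m = ExpressionMatrix(df)
        pair = CohortPair("c", tuple(cols[n1:]), tuple(cols[:n1]))
        tab = de_table_for_cohorts(m, [pair]).set_index("gene")
        np.testing.assert_allclose(tab["t"], limma.loc[tab.index, "t"], atol=1e-10)
        np.testing.assert_allclose(tab["p"], limma.loc[tab.index, "p"], atol=1e-10)

    def test_arm_exchange_negates_t(self, rng, two_arm_pair):
        m = random_matrix(rng, 12, 6)
        prior = VariancePrior(4.0, 1.0)
        fwd = moderated_t_table(m, two_arm_pair, prior)
        rev = moderated_t_table(
            m,
            CohortPair("c1", two_arm_pair.resistant_samples, two_arm_pair.sensitive_samples),
            prior,
        )
        np.testing.assert_allclose(fwd["t"], -rev["t"], atol=1e-12)
        np.testing.assert_allclose(fwd["p"], rev["p"], atol=1e-12)


class TestTypeIError:
    def test_null_rejection_rate_is_nominal(self):
        """No planted effect, n=3 vs 3: fraction of p <= 0.05 stays nominal."""
        rng = np.random.default_rng(99)
        n_genes, reps = 2000, 200
        pair = CohortPair("c", ("S0", "S1", "S2"), ("S3", "S4", "S5"))
        hits = total = 0
        for _ in range(reps):
            vals = rng.normal(8, 1, (n_genes, 6))
            m = ExpressionMatrix(
                pd.DataFrame(vals, index=[f"G{i}" for i in range(n_genes)],
                             columns=[f"S{j}" for j in range(6)])
            )
            tab = de_table_for_cohorts(m, [pair])
            hits += int((tab["p"] <= 0.05).sum())
            total += n_genes
        rate = hits / total
        assert 0.04 <= rate <= 0.06


class TestPairedT:
    def test_identical_vectors(self):
        t, df, p = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, df, p) == (0.0, 2, 1.0)

    def test_constant_nonzero_difference_degenerate(self):
        t, df, p = paired_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert np.isinf(t) and t < 0
        assert p == 0.0

    def test_matches_textbook_formula_and_scipy(self, rng):
        a = rng.normal(5, 1, 7)
        b = rng.normal(4.5, 1, 7)
        t, df, p = paired_t_test(a, b)
        d = a - b
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(7))
        p_oracle = 2 * stats.t.sf(abs(t_oracle), 6)
        assert t == pytest.approx(t_oracle, rel=1e-12)
        assert df == 6
        assert p == pytest.approx(p_oracle, rel=1e-12)
        sp = stats.ttest_rel(a, b)
        assert t == pytest.approx(sp.statistic, rel=1e-12)
        assert p == pytest.approx(sp.pvalue, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0], [1.0, 2.0, 3.0])
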