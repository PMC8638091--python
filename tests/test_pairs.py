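"""CILP core: products, paired/regression tests, BH FDR, DCL calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import dclink as dl
from dclink.pairs import SingularDesignError


# ---------------------------------------------------------------- oracles
def bh_stepup_oracle(p):
    """Hand step-up: q_(i) = min over j >= i of p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def ols_normal_equations_oracle(y, X):
    """From-scratch OLS: beta, two-sided t p-values via (X'X)^-1."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df=df)
    return beta, p


# ---------------------------------------------------------------- z-score
class TestZscoreGenes:
    def test_three_point_row(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        z, rejected = dl.zscore_genes(m)
        assert np.allclose(z.loc["g"], [-1.0, 0.0, 1.0])
        assert rejected == []

    def test_constant_row_excluded_not_crashed(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 4.0]], index=["flat", "ok"],
                         columns=list("abc"))
        z, rejected = dl.zscore_genes(m)
        assert rejected == ["flat"]
        assert list(z.index) == ["ok"]

    def test_mean_zero_sd_one(self, rng):
        m = pd.DataFrame(rng.standard_normal((5, 20)))
        z, _ = dl.zscore_genes(m)
        assert np.abs(z.mean(axis=1)).max() < 1e-12
        assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-12)


# --------------------------------------------------- product correlation
class TestProductCorrelation:
    def test_self_correlation_products(self):
        z = np.array([-1.0, 0.0, 1.0])
        p = dl.product_correlation(z, z)
        assert np.allclose(p, [1.0, 0.0, 1.0])
        assert p.sum() / (len(z) - 1) == pytest.approx(1.0)

    def test_anti_correlation(self):
        z = np.array([-1.0, 0.0, 1.0])
        p = dl.product_correlation(z, -z)
        assert (p <= 0).all()
        assert p.sum() / (len(z) - 1) == pytest.approx(-1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            dl.product_correlation(np.zeros(3), np.zeros(4))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1), st.sampled_from([5, 50, 500]))
    def test_product_identity_equals_pearson(self, seed, n):
        """sum(p_i)/(n-1) must equal Pearson r computed by the covariance formula."""
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal(n), rng.standard_normal(n)
        za = (a - a.mean()) / a.std(ddof=1)
        zb = (b - b.mean()) / b.std(ddof=1)
        identity = dl.product_correlation(za, zb).sum() / (n - 1)
        assert identity == pytest.approx(stats.pearsonr(a, b)[0], abs=1e-10)


# ------------------------------------------------------- paired CILP test
class TestCilpTestPaired:
    def test_identical_products_give_null_result(self):
        p = np.array([0.2, -0.1, 0.4, 0.3])
        res = dl.cilp_test_paired(p, p)
        assert res.t == 0.0 and res.p == 1.0

    def test_zero_variance_difference_flagged_degenerate(self):
        res = dl.cilp_test_paired(np.zeros(4), np.ones(4))
        assert res.degenerate
        assert res.p == dl.DEGENERATE_P

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3"):
            dl.cilp_test_paired(np.zeros(2), np.ones(2))

    def test_matches_t_distribution_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 40))
            pn, pt = rng.standard_normal(n), rng.standard_normal(n)
            res = dl.cilp_test_paired(pn, pt)
            d = pt - pn
            t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
            p = 2 * stats.t.sf(abs(t), df=n - 1)
            assert res.t == pytest.approx(t, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_equals_intercept_only_ols_on_differences(self, rng):
        """For paired data the paired t-test is the intercept-only regression
        of the product differences."""
        n = 25
        pn, pt = rng.standard_normal(n), rng.standard_normal(n)
        res = dl.cilp_test_paired(pn, pt)
        _, p = ols_normal_equations_oracle(pt - pn, np.ones((n, 1)))
        assert res.p == pytest.approx(p[0], abs=1e-10)

    def test_type_one_error_calibrated_under_null(self, rng):
        n_pairs, n_subj = 1000, 20
        pn = rng.standard_normal((n_pairs, n_subj))
        pt = rng.standard_normal((n_pairs, n_subj))
        rejections = sum(
            dl.cilp_test_paired(pn[i], pt[i]).p < 0.05 for i in range(n_pairs)
        )
        band = 3 * np.sqrt(0.05 * 0.95 / n_pairs)
        assert abs(rejections / n_pairs - 0.05) < band


# --------------------------------------------------- regression CILP test
class TestCilpTestRegression:
    def test_strong_planted_group_effect(self, rng):
        n = 200
        group = np.repeat([0.0, 1.0], n // 2)
        za, zb = rng.standard_normal(n), rng.standard_normal(n)
        products = 2.0 * group + 0.1 * rng.standard_normal(n)
        res = dl.cilp_test_regression(products, group, za, zb)
        assert res.p_group < 1e-10

    def test_null_group_pvalues_roughly_uniform(self, rng):
        n = 100
        group = np.repeat([0.0, 1.0], n // 2)
        ps = []
        for _ in range(200):
            products = rng.standard_normal(n)
            res = dl.cilp_test_regression(
                products, group, rng.standard_normal(n), rng.standard_normal(n)
            )
            ps.append(res.p_group)
        assert stats.kstest(ps, "uniform").pvalue > 0.001

    def test_matches_normal_equations_oracle(self, rng):
        n = 60
        group = np.repeat([0.0, 1.0], n // 2)
        za, zb = rng.standard_normal(n), rng.standard_normal(n)
        products = 0.5 * group + 0.3 * za + rng.standard_normal(n)
        res = dl.cilp_test_regression(products, group, za, zb)
        X = np.column_stack([np.ones(n), group, za, zb])
        beta, p = ols_normal_equations_oracle(products, X)
        assert res.coef_group == pytest.approx(beta[1], abs=1e-10)
        assert res.p_group == pytest.approx(p[1], abs=1e-10)
        assert res.p_cov_a == pytest.approx(p[2], abs=1e-10)
        assert res.p_cov_b == pytest.approx(p[3], abs=1e-10)

    def test_rank_deficiency_names_pair(self, rng):
        n = 30
        group = np.repeat([0.0, 1.0], n // 2)
        za = rng.standard_normal(n)
        with pytest.raises(SingularDesignError, match="GA.*GB"):
            dl.cilp_test_regression(rng.standard_normal(n), group, za, za,
                                    pair=("GA", "GB"))


# --------------------------------------------------------------- BH FDR
class TestBhFdr:
    def test_hand_computed_stepup_example(self):
        assert np.allclose(dl.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert dl.bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_ones(self):
        assert np.allclose(dl.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dl.bh_fdr([0.5, 1.5])

    def test_q_at_least_p(self, rng):
        p = rng.uniform(size=50)
        assert (dl.bh_fdr(p) >= p - 1e-15).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_oracle_and_permutation_invariant(self, p):
        p = np.asarray(p)
        q = dl.bh_fdr(p)
        assert np.allclose(q, bh_stepup_oracle(p), atol=1e-12)
        # monotone nondecreasing in sorted-p order
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()
        # invariant to input permutation (after unsorting)
        perm = np.random.default_rng(0).permutation(len(p))
        q_perm = dl.bh_fdr(p[perm])
        assert np.allclose(q_perm, q[perm], atol=1e-12)


# ------------------------------------------------- DCL calling and labels
def _screen_planted(seed):
    cfg = dl.SimConfig(
        n_subjects=60, n_extra_tumor=0, n_genes=240,
        planted_dc_pairs=[(f"G{2*i+1:04d}", f"G{2*i+2:04d}", 0.8, 0.0) for i in range(10)],
        null_pairs=100, seed=seed,
    )
    c = dl.generate_cohort(cfg)
    pairing = pd.DataFrame({
        "subject_id": [s[:-2] for s in c.expr_normal.columns],
        "normal_sample": c.expr_normal.columns,
        "tumor_sample": c.expr_tumor.columns,
    })
    results, _ = dl.cilp_screen_paired(c.expr_normal, c.expr_tumor, c.pairs,
                                       pairing, fdr_cutoff=0.3)
    truth = set(zip(c.truth_dc_pairs["gene_a"], c.truth_dc_pairs["gene_b"]))
    return results, truth


class TestCallDcls:
    def test_zero_cutoff_returns_empty(self, rng):
        results = pd.DataFrame({
            "gene_a": ["a"], "gene_b": ["b"], "p_group": [0.2], "fdr_group": [0.2],
        })
        assert len(dl.call_dcls(results, 0.0)) == 0

    def test_single_small_p_included_at_default_cutoff(self):
        results = pd.DataFrame({
            "gene_a": ["a"], "gene_b": ["b"],
            "p_group": [0.01], "fdr_group": dl.bh_fdr([0.01]),
        })
        assert len(dl.call_dcls(results, 0.3)) == 1

    def test_planted_recall_and_fdr_over_replicates(self):
        """10 planted pairs (rho 0.8 -> 0) among 100 null, 60 subjects:
        recall >= 0.8 and empirical FDR <= 2x nominal over 20 replicates."""
        recalls, fdps = [], []
        for seed in range(20):
            results, truth = _screen_planted(seed)
            dcls = dl.call_dcls(results, 0.3)
            called = set(zip(dcls["gene_a"], dcls["gene_b"]))
            recalls.append(len(called & truth) / len(truth))
            fdps.append(len(called - truth) / max(len(called), 1))
        assert np.mean(recalls) >= 0.8
        assert np.mean(fdps) <= 0.6


class TestClassifyDeDependence:
    def test_all_unit_covariate_ps_are_independent(self):
        results = pd.DataFrame({
            "gene_a": list("abc"), "gene_b": list("xyz"),
            "p_cov_a": [1.0] * 3, "p_cov_b": [1.0] * 3,
        })
        out = dl.classify_de_dependence(results, 0.1)
        assert (out["de_dependence"] == "DE-independent").all()

    def test_one_tiny_covariate_p_flags_that_pair(self):
        results = pd.DataFrame({
            "gene_a": list("abcd"), "gene_b": list("wxyz"),
            "p_cov_a": [1e-12, 0.9, 0.8, 0.7], "p_cov_b": [0.6] * 4,
        })
        out = dl.classify_de_dependence(results, 0.1)
        assert out.loc[0, "de_dependence"] == "DE-dependent"
        assert (out.loc[1:, "de_dependence"] == "DE-independent").all()

    def test_planted_product_expression_dependence_detected(self, rng):
        """Pairs whose products track z_a^2 should classify DE-dependent."""
        n = 120
        group = np.repeat([0.0, 1.0], n // 2)
        rows = []
        n_dependent = 30
        for i in range(n_dependent):
            za, zb = rng.standard_normal(n), rng.standard_normal(n)
            products = za * za - 1 + 0.3 * rng.standard_normal(n)
            # a linear probe of products on za is weak for za^2; plant a
            # linear component too, as expression-coupled products have
            products += 0.8 * za
            res = dl.cilp_test_regression(products, group, za, zb)
            rows.append(("a%d" % i, "b%d" % i, res.p_cov_a, res.p_cov_b))
        for i in range(50):
            za, zb = rng.standard_normal(n), rng.standard_normal(n)
            res = dl.cilp_test_regression(rng.standard_normal(n), group, za, zb)
            rows.append(("c%d" % i, "d%d" % i, res.p_cov_a, res.p_cov_b))
        results = pd.DataFrame(rows, columns=["gene_a", "gene_b", "p_cov_a", "p_cov_b"])
        out = dl.classify_de_dependence(results, 0.1)
        rate = (out.iloc[:n_dependent]["de_dependence"] == "DE-dependent").mean()
        assert rate >= 0.8


class TestScreens:
    def test_paired_screen_product_identity(self, planted_cohort):
        c = planted_cohort
        pairing = pd.DataFrame({
            "subject_id": [s[:-2] for s in c.expr_normal.columns],
            "normal_sample": c.expr_normal.columns,
            "tumor_sample": [s + "-T" for s in [x[:-2] for x in c.expr_normal.columns]],
        })
        results, rejects = dl.cilp_screen_paired(
            c.expr_normal, c.expr_tumor, c.pairs, pairing
        )
        assert len(rejects) == 0
        sub_t = c.expr_tumor[pairing["tumor_sample"]]
        for _, row in results.head(10).iterrows():
            r = np.corrcoef(sub_t.loc[row.gene_a], sub_t.loc[row.gene_b])[0, 1]
            assert row.pcc_tumor == pytest.approx(r, abs=1e-10)

    def test_regression_screen_flags_planted_pairs(self, planted_cohort):
        c = planted_cohort
        results, _ = dl.cilp_screen_regression(
            c.expr_normal, c.expr_tumor, c.pairs, fdr_cutoff=0.1
        )
        truth = set(zip(c.truth_dc_pairs["gene_a"], c.truth_dc_pairs["gene_b"]))
        called = set(zip(results.loc[results["is_dcl"], "gene_a"],
                         results.loc[results["is_dcl"], "gene_b"]))
        assert truth <= called
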