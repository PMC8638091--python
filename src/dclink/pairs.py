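"""Sample-wise product correlations (CILP) and differential-coexpression tests.

The core identity: after z-scoring each gene across the samples of one
condition (mean 0, SD 1 with the n-1 denominator), the per-sample products
p_i = z_a[i] * z_b[i] satisfy sum(p_i) / (n - 1) = Pearson r of the two
genes in that condition. The products behave like a per-sample coexpression
measurement, so ordinary tests (paired t, OLS with covariates) compare
coexpression between conditions.

Two screening entry points mirror the two study designs:

- :func:`cilp_screen_paired` — per-subject product differences tested with a
  paired t-test (the regression model degenerates to this for matched
  normal/tumor samples without covariates).
- :func:`cilp_screen_regression` — products regressed on the condition
  indicator with the two genes' z-scored expression vectors as covariates;
  the covariate p-values feed the DE-dependence classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: smallest positive normal double; stands in for p-values that underflow
#: (zero-variance difference with nonzero mean).
DEGENERATE_P = float(np.finfo(float).tiny)

DE_DEPENDENT = "DE-dependent"
DE_INDEPENDENT = "DE-independent"


class ZeroVarianceGeneError(ValueError):
    """A gene with zero variance cannot be z-scored."""


class SingularDesignError(ValueError):
    """The regression design matrix is rank deficient."""


def zscore_genes(m: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Center and scale each gene row to mean 0, sample SD 1 (ddof=1).

    Returns the z-scored matrix restricted to genes with nonzero variance,
    plus the list of excluded zero-variance gene ids (the rejects report).
    """
    values = m.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    rejected = m.index[~keep].tolist()
    centered = values[keep] - values[keep].mean(axis=1, keepdims=True)
    z = centered / sd[keep, None]
    return pd.DataFrame(z, index=m.index[keep], columns=m.columns), rejected


def product_correlation(z_a: np.ndarray, z_b: np.ndarray) -> np.ndarray:
    """Element-wise products of two z-scored profiles (the per-sample p_i)."""
    z_a = np.asarray(z_a, dtype=float)
    z_b = np.asarray(z_b, dtype=float)
    if z_a.shape != z_b.shape:
        raise ValueError(f"length mismatch: {z_a.shape} vs {z_b.shape}")
    return z_a * z_b


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    p: float
    mean_diff: float
    n: int
    degenerate: bool = False


def cilp_test_paired(
    products_normal: np.ndarray, products_tumor: np.ndarray
) -> PairedTestResult:
    """Two-sided paired t-test on per-subject product differences (tumor - normal).

    Requires at least 3 complete subject pairs. A zero-variance nonzero
    difference vector cannot be assigned a finite t statistic; its p-value is
    set to the smallest representable positive double and flagged degenerate.
    """
    pn = np.asarray(products_normal, dtype=float)
    pt = np.asarray(products_tumor, dtype=float)
    if pn.shape != pt.shape:
        raise ValueError("paired product vectors differ in length")
    n = pn.size
    if n < 3:
        raise ValueError(f"paired CILP test undefined for {n} < 3 subject pairs")
    diff = pt - pn
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(t=0.0, p=1.0, mean_diff=0.0, n=n)
        return PairedTestResult(
            t=np.inf if mean > 0 else -np.inf,
            p=DEGENERATE_P,
            mean_diff=mean,
            n=n,
            degenerate=True,
        )
    t = mean / (sd / np.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return PairedTestResult(t=float(t), p=p, mean_diff=mean, n=n)


@dataclass(frozen=True)
class RegressionTestResult:
    p_group: float
    p_cov_a: float
    p_cov_b: float
    coef_group: float
    n: int


def cilp_test_regression(
    products: np.ndarray,
    group: np.ndarray,
    z_a: np.ndarray,
    z_b: np.ndarray,
    pair: tuple[str, str] | None = None,
) -> RegressionTestResult:
    """OLS of products on (intercept, condition indicator, z_a, z_b).

    Returns two-sided t-test p-values for the condition coefficient and each
    expression covariate. Raises :class:`SingularDesignError` (naming the
    pair when given) if the design matrix is rank deficient.
    """
    y = np.asarray(products, dtype=float)
    X = np.column_stack(
        [
            np.asarray(group, dtype=float),
            np.asarray(z_a, dtype=float),
            np.asarray(z_b, dtype=float),
        ]
    )
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        tag = f" for pair {pair}" if pair else ""
        raise SingularDesignError(f"rank-deficient CILP design matrix{tag}")
    fit = sm.OLS(y, X).fit()
    return RegressionTestResult(
        p_group=float(fit.pvalues[1]),
        p_cov_a=float(fit.pvalues[2]),
        p_cov_b=float(fit.pvalues[3]),
        coef_group=float(fit.params[1]),
        n=y.size,
    )


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, order preserved)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pair_products(
    z: pd.DataFrame, pairs: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Per-sample products for every pair with both genes z-scored.

    Returns (products, za, zb) as pairs x samples arrays, the retained pair
    rows, and the rejected pair rows (a gene missing after z-scoring).
    """
    present = pairs["gene_a"].isin(z.index) & pairs["gene_b"].isin(z.index)
    kept = pairs[present].reset_index(drop=True)
    rejected = pairs[~present].reset_index(drop=True)
    za = z.loc[kept["gene_a"]].to_numpy()
    zb = z.loc[kept["gene_b"]].to_numpy()
    return za * zb, za, zb, kept, rejected


def pair_pcc(z: pd.DataFrame, pairs: pd.DataFrame) -> np.ndarray:
    """Pearson correlations per pair via the product identity sum(p_i)/(n-1)."""
    products, _, _, kept, rejected = _pair_products(z, pairs)
    if len(rejected):
        raise ZeroVarianceGeneError(
            f"pairs reference zero-variance or absent genes: {rejected.to_numpy()[:5]}"
        )
    n = z.shape[1]
    return products.sum(axis=1) / (n - 1)


def cilp_screen_paired(
    normal: pd.DataFrame,
    tumor: pd.DataFrame,
    pairs: pd.DataFrame,
    pairing: pd.DataFrame,
    fdr_cutoff: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired-design differential-coexpression screen over a pair list.

    Each gene is z-scored within its condition; per-subject products are
    compared tumor vs normal with a paired t-test, and the p-value family is
    BH-adjusted. Returns (results, rejects): results has one row per testable
    pair with pcc_normal, pcc_tumor, t, mean_diff, p_group, fdr_group,
    is_dcl; rejects lists pairs dropped for zero-variance genes.

    `pairing` columns: subject_id, normal_sample, tumor_sample.
    """
    if len(pairing) < 3:
        raise ValueError("paired screen needs at least 3 complete subject pairs")
    zn, _ = zscore_genes(normal[pairing["normal_sample"]])
    zt, _ = zscore_genes(tumor[pairing["tumor_sample"]])
    common = zn.index.intersection(zt.index)
    zn, zt = zn.loc[common], zt.loc[common]
    prod_n, _, _, kept_n, _ = _pair_products(zn, pairs)
    prod_t, _, _, kept, rejects = _pair_products(zt, pairs)
    if not kept.equals(kept_n):  # defensive: same index restriction on both
        raise AssertionError("pair bookkeeping diverged between conditions")

    n = len(pairing)
    diffs = prod_t - prod_n
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    degenerate = sd == 0
    p[degenerate & (mean != 0)] = DEGENERATE_P
    p[degenerate & (mean == 0)] = 1.0
    t[degenerate & (mean == 0)] = 0.0

    results = kept.copy()
    results["pcc_normal"] = prod_n.sum(axis=1) / (n - 1)
    results["pcc_tumor"] = prod_t.sum(axis=1) / (n - 1)
    results["mean_diff"] = mean
    results["t"] = t
    results["p_group"] = p
    results["degenerate"] = degenerate
    results["fdr_group"] = bh_fdr(p)
    results["is_dcl"] = results["fdr_group"] <= fdr_cutoff
    return results, rejects


def cilp_screen_regression(
    normal: pd.DataFrame,
    tumor: pd.DataFrame,
    pairs: pd.DataFrame,
    fdr_cutoff: float = 0.1,
    de_dependence_fdr: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Regression-form screen with expression covariates (non-paired design).

    Samples from both conditions are stacked; products are regressed on the
    condition indicator plus the two z-scored expression vectors. Group
    p-values are BH-adjusted as one family; covariate p-values are pooled
    into a single family across all pairs before adjustment, and a pair is
    labelled DE-dependent when either covariate's FDR falls below
    `de_dependence_fdr`.
    """
    zn, _ = zscore_genes(normal)
    zt, _ = zscore_genes(tumor)
    common = zn.index.intersection(zt.index)
    zn, zt = zn.loc[common], zt.loc[common]
    prod_n, za_n, zb_n, kept_n, _ = _pair_products(zn, pairs)
    prod_t, za_t, zb_t, kept, rejects = _pair_products(zt, pairs)
    if not kept.equals(kept_n):
        raise AssertionError("pair bookkeeping diverged between conditions")

    n_n, n_t = zn.shape[1], zt.shape[1]
    group = np.concatenate([np.zeros(n_n), np.ones(n_t)])
    rows = []
    for i in range(len(kept)):
        res = cilp_test_regression(
            np.concatenate([prod_n[i], prod_t[i]]),
            group,
            np.concatenate([za_n[i], za_t[i]]),
            np.concatenate([zb_n[i], zb_t[i]]),
            pair=(kept.at[i, "gene_a"], kept.at[i, "gene_b"]),
        )
        rows.append((res.p_group, res.p_cov_a, res.p_cov_b, res.coef_group))
    results = kept.copy()
    cols = np.array(rows) if rows else np.empty((0, 4))
    results["p_group"] = cols[:, 0] if len(rows) else []
    results["p_cov_a"] = cols[:, 1] if len(rows) else []
    results["p_cov_b"] = cols[:, 2] if len(rows) else []
    results["coef_group"] = cols[:, 3] if len(rows) else []
    results["pcc_normal"] = prod_n.sum(axis=1) / (n_n - 1)
    results["pcc_tumor"] = prod_t.sum(axis=1) / (n_t - 1)
    results["fdr_group"] = bh_fdr(results["p_group"].to_numpy())
    results["is_dcl"] = results["fdr_group"] <= fdr_cutoff
    results = classify_de_dependence(results, fdr_cutoff=de_dependence_fdr)
    return results, rejects


def classify_de_dependence(
    results: pd.DataFrame, fdr_cutoff: float = 0.1
) -> pd.DataFrame:
    """Split pairs by whether products depend on either gene's expression.

    Covariate p-values from all tested pairs form one pooled BH family; a
    pair is DE-dependent iff min(fdr_cov_a, fdr_cov_b) < `fdr_cutoff`.
    """
    out = results.copy()
    if len(out) == 0:
        for col in ("fdr_cov_a", "fdr_cov_b"):
            out[col] = []
        out["de_dependence"] = pd.Series([], dtype=str)
        return out
    pooled = np.concatenate([out["p_cov_a"].to_numpy(), out["p_cov_b"].to_numpy()])
    q = bh_fdr(pooled)
    k = len(out)
    out["fdr_cov_a"] = q[:k]
    out["fdr_cov_b"] = q[k:]
    dependent = np.minimum(out["fdr_cov_a"], out["fdr_cov_b"]) < fdr_cutoff
    out["de_dependence"] = np.where(dependent, DE_DEPENDENT, DE_INDEPENDENT)
    return out


def call_dcls(results: pd.DataFrame, fdr_cutoff: float) -> pd.DataFrame:
    """Flagged DCL subset (fdr_group <= cutoff), sorted by p_group ascending."""
    if len(results) == 0:
        return results.copy()
    dcls = results[results["fdr_group"] <= fdr_cutoff]
    return dcls.sort_values("p_group", kind="mergesort").reset_index(drop=True)
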