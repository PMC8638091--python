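"""Survival screening of differentially coexpressed links.

For each DCL, product correlations are computed across the tumor survival
cohort (subjects who contributed paired samples to the DC screen excluded,
z-scoring redone across the remaining cohort), the per-subject values are
dichotomized at the cohort median (ties to low), and the high vs low strata
are compared with a two-group log-rank test. Log-rank p-values are
BH-adjusted across all DCLs screened in the run; FDR <= cutoff flags a
prognosis DCL.

The log-rank statistic is implemented directly so the screen can report the
direction of the effect (sign of observed-minus-expected deaths in the
high-coexpression stratum); lifelines supplies Kaplan-Meier coordinates for
plotting-oriented export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .pairs import bh_fdr, zscore_genes

logger = logging.getLogger(__name__)

HIGH, LOW = "high", "low"


def cohort_product_correlations(
    tumor: pd.DataFrame,
    pairs: pd.DataFrame,
    exclude_samples: Sequence[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Product-correlation values per (pair, sample) over the retained cohort.

    Genes are centered and scaled across the retained tumor samples only.
    Returns (matrix, rejects): the matrix is pairs x samples with a
    "gene_a|gene_b" row index; rejects lists pairs dropped for zero-variance
    genes.
    """
    keep = [s for s in tumor.columns if s not in set(exclude_samples)]
    if len(keep) == 0:
        raise ValueError("all tumor samples excluded; survival cohort is empty")
    if len(keep) < 10:
        logger.warning("survival cohort has only %d samples", len(keep))
    z, _ = zscore_genes(tumor[keep])
    ok = pairs["gene_a"].isin(z.index) & pairs["gene_b"].isin(z.index)
    kept = pairs[ok].reset_index(drop=True)
    rejects = pairs[~ok].reset_index(drop=True)
    products = z.loc[kept["gene_a"]].to_numpy() * z.loc[kept["gene_b"]].to_numpy()
    index = kept["gene_a"] + "|" + kept["gene_b"]
    return pd.DataFrame(products, index=index, columns=keep), rejects


def dichotomize_by_median(values: np.ndarray) -> np.ndarray:
    """Boolean high-coexpression indicator: value strictly above the median.

    Values at or below the median go to the low stratum, so ties never split
    a stratum nondeterministically. An all-identical vector yields all-low.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("median dichotomization needs at least 2 values")
    high = values > np.median(values)
    if not high.any():
        logger.warning("degenerate dichotomization: no value above the median")
    return high


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    p: float
    o_minus_e_high: float
    n_high: int
    n_low: int
    n_events: int

    @property
    def worse_group(self) -> str:
        """Stratum with more deaths than expected under the null."""
        if self.o_minus_e_high > 0:
            return HIGH
        if self.o_minus_e_high < 0:
            return LOW
        return "none"


def logrank_test(
    time: np.ndarray, event: np.ndarray, high: np.ndarray
) -> LogrankResult:
    """Standard two-group log-rank test.

    At each distinct event time, deaths observed in the high stratum minus
    the hypergeometric expectation are accumulated along with the variance;
    the squared ratio is chi-square with 1 df. Zero events in total yields
    p = 1 (flagged by n_events == 0); an empty stratum is an error.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    high = np.asarray(high, dtype=bool)
    if time.shape != event.shape or time.shape != high.shape:
        raise ValueError("time, event and group vectors must share a shape")
    n_high, n_low = int(high.sum()), int((~high).sum())
    if n_high == 0 or n_low == 0:
        raise ValueError("log-rank test undefined with an empty stratum")
    n_events = int(event.sum())
    if n_events == 0:
        return LogrankResult(0.0, 1.0, 0.0, n_high, n_low, 0)

    event_times = np.unique(time[event == 1])
    o_minus_e = 0.0
    variance = 0.0
    for t in event_times:
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & high).sum())
        dying = (time == t) & (event == 1)
        d = int(dying.sum())
        d1 = int((dying & high).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if variance == 0:
        return LogrankResult(0.0, 1.0, float(o_minus_e), n_high, n_low, n_events)
    chi2 = o_minus_e * o_minus_e / variance
    p = float(stats.chi2.sf(chi2, df=1))
    return LogrankResult(float(chi2), p, float(o_minus_e), n_high, n_low, n_events)


def screen_prognosis(
    tumor: pd.DataFrame,
    dcls: pd.DataFrame,
    survival: pd.DataFrame,
    sample_to_subject: Mapping[str, str],
    exclude_subjects: Sequence[str] = (),
    fdr_cutoff: float = 0.3,
) -> pd.DataFrame:
    """Log-rank screen of every DCL against overall survival.

    `dcls` is a pair table (gene_a, gene_b); `sample_to_subject` maps tumor
    sample ids to clinical subject ids. Subjects in `exclude_subjects` (the
    normal-paired contributors) and subjects lacking either expression or
    survival data are dropped; the dropped count is logged.

    Returns one row per testable pair with stratum sizes, chi-square, p,
    BH FDR over the screened family, the worse-survival stratum and the
    is_prognosis_dcl flag.
    """
    excluded = set(exclude_subjects)
    surv = survival.set_index("subject_id")
    cols, subjects = [], []
    for s in tumor.columns:
        subj = sample_to_subject.get(s)
        if subj is None or subj in excluded or subj not in surv.index:
            continue
        cols.append(s)
        subjects.append(subj)
    dropped = tumor.shape[1] - len(cols)
    if dropped:
        logger.info("prognosis screen: dropped %d tumor samples without usable subjects", dropped)
    if len(cols) < 2:
        raise ValueError("fewer than 2 tumor samples with survival data")

    exclude_samples = [s for s in tumor.columns if s not in set(cols)]
    products, _ = cohort_product_correlations(tumor, dcls, exclude_samples=exclude_samples)
    time = surv.loc[subjects, "time"].to_numpy(dtype=float)
    event = surv.loc[subjects, "event"].to_numpy(dtype=int)

    rows = []
    for key, values in products.iterrows():
        gene_a, gene_b = key.split("|")
        high = dichotomize_by_median(values.to_numpy())
        if high.all() or not high.any():
            # degenerate split: untestable, keep with p = 1
            rows.append((gene_a, gene_b, int(high.sum()), int((~high).sum()),
                         0.0, 1.0, "none"))
            continue
        res = logrank_test(time, event, high)
        rows.append(
            (gene_a, gene_b, res.n_high, res.n_low, res.chi_square, res.p, res.worse_group)
        )
    out = pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "n_high", "n_low", "chi_square", "p", "worse_group"],
    )
    out["fdr"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    out["is_prognosis_dcl"] = out["fdr"] <= fdr_cutoff if len(out) else []
    return out


def call_prognosis_dcls(results: pd.DataFrame, fdr_cutoff: float) -> pd.DataFrame:
    """Flagged prognosis-DCL subset sorted by p ascending."""
    if len(results) == 0:
        return results.copy()
    hits = results[results["fdr"] <= fdr_cutoff]
    return hits.sort_values("p", kind="mergesort").reset_index(drop=True)


def km_coordinates(
    time: np.ndarray, event: np.ndarray, high: np.ndarray
) -> pd.DataFrame:
    """Kaplan-Meier survival-curve coordinates for the two strata."""
    frames = []
    for label, mask in ((HIGH, np.asarray(high, bool)), (LOW, ~np.asarray(high, bool))):
        kmf = KaplanMeierFitter()
        kmf.fit(np.asarray(time)[mask], np.asarray(event)[mask], label=label)
        df = kmf.survival_function_.reset_index()
        df.columns = ["time", "survival"]
        df["group"] = label
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
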