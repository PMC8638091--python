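"""Global correlation-landscape diagnostics between two conditions.

Given a pair list and the normal/tumor expression matrices these helpers
describe how the correlation structure changes as a whole: per-pair
condition-wise Pearson correlations, the Strengthened/Weakened partition of
pairs by absolute-correlation change, the regression slope of tumor PCC on
normal PCC (slope < 1 signals global attenuation), half-thresholded
candidate-pair selection, and the asymmetric heatmap matrix (normal in the
lower triangle, tumor in the upper).
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .pairs import zscore_genes

STRENGTHENED = "Strengthened"
WEAKENED = "Weakened"

DIFFERENTLY_SIGNED = "differently signed"
SAME_SIGNED_POSITIVE = "same-signed positive"
SAME_SIGNED_NEGATIVE = "same-signed negative"


def n_pairs(k: int) -> int:
    """Number of unordered gene pairs among k genes: k(k-1)/2."""
    return k * (k - 1) // 2


def all_pairs(genes: Sequence[str]) -> pd.DataFrame:
    """Enumerate all unordered pairs of a gene list, in lexicographic order."""
    return pd.DataFrame(combinations(genes, 2), columns=["gene_a", "gene_b"])


def sign_pattern(pcc_normal: float, pcc_tumor: float) -> str:
    # a PCC of exactly 0 counts as positive (degenerate, near-measure-zero)
    pos_n = pcc_normal >= 0
    pos_t = pcc_tumor >= 0
    if pos_n != pos_t:
        return DIFFERENTLY_SIGNED
    return SAME_SIGNED_POSITIVE if pos_n else SAME_SIGNED_NEGATIVE


def condition_pccs(
    pairs: pd.DataFrame, normal: pd.DataFrame, tumor: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Condition-wise PCC per pair, with strength-change and sign labels.

    Returns (table, rejects). Pairs touching a zero-variance gene in either
    condition go to the rejects table; unknown gene ids raise KeyError.
    """
    for m, label in ((normal, "normal"), (tumor, "tumor")):
        missing = sorted(
            (set(pairs["gene_a"]) | set(pairs["gene_b"])) - set(m.index)
        )
        if missing:
            raise KeyError(f"genes absent from {label} matrix: {missing[:10]}")
    zn, _ = zscore_genes(normal)
    zt, _ = zscore_genes(tumor)
    ok = (
        pairs["gene_a"].isin(zn.index)
        & pairs["gene_b"].isin(zn.index)
        & pairs["gene_a"].isin(zt.index)
        & pairs["gene_b"].isin(zt.index)
    )
    kept = pairs[ok].reset_index(drop=True)
    rejects = pairs[~ok].reset_index(drop=True)
    if len(kept) == 0:
        table = kept.copy()
        for col in ("pcc_normal", "pcc_tumor"):
            table[col] = []
        table["strength_change"] = pd.Series([], dtype=str)
        table["sign_pattern"] = pd.Series([], dtype=str)
        return table, rejects
    pcc_n = (
        (zn.loc[kept["gene_a"]].to_numpy() * zn.loc[kept["gene_b"]].to_numpy()).sum(axis=1)
        / (zn.shape[1] - 1)
    )
    pcc_t = (
        (zt.loc[kept["gene_a"]].to_numpy() * zt.loc[kept["gene_b"]].to_numpy()).sum(axis=1)
        / (zt.shape[1] - 1)
    )
    table = kept.copy()
    table["pcc_normal"] = pcc_n
    table["pcc_tumor"] = pcc_t
    # ties in absolute PCC count as Weakened (conservative for attenuation)
    table["strength_change"] = np.where(
        np.abs(pcc_t) > np.abs(pcc_n), STRENGTHENED, WEAKENED
    )
    table["sign_pattern"] = [sign_pattern(a, b) for a, b in zip(pcc_n, pcc_t)]
    return table, rejects


def strength_fractions(table: pd.DataFrame) -> tuple[float, float]:
    """(fraction Strengthened, fraction Weakened); they sum to 1 exactly."""
    if len(table) == 0:
        raise ValueError("strength fractions undefined for an empty pair table")
    strengthened = float((table["strength_change"] == STRENGTHENED).mean())
    return strengthened, 1.0 - strengthened


def fit_cross_condition_slope(table: pd.DataFrame) -> tuple[float, float]:
    """OLS slope and intercept of pcc_tumor regressed on pcc_normal."""
    x = table["pcc_normal"].to_numpy(dtype=float)
    y = table["pcc_tumor"].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("cross-condition slope undefined: degenerate regressor")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def half_threshold_pairs(
    genes: Sequence[str],
    normal: pd.DataFrame,
    tumor: pd.DataFrame,
    top_fraction: float = 0.01,
) -> pd.DataFrame:
    """Half-thresholding: keep pairs strong in EITHER condition.

    Among all k(k-1)/2 pairs of `genes`, selects the union of the top
    ceil(top_fraction * M) pairs by |PCC| in each condition. Ties at either
    cutoff are all admitted, so the selection may slightly exceed the
    nominal count. Fewer than 2 genes yields an empty selection.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must lie in (0, 1]")
    genes = list(genes)
    if len(genes) < 2:
        return pd.DataFrame(columns=["gene_a", "gene_b", "pcc_normal", "pcc_tumor"])
    pairs = all_pairs(genes)
    table, _ = condition_pccs(pairs, normal, tumor)
    m = len(table)
    top = int(np.ceil(top_fraction * m))
    selected = np.zeros(m, dtype=bool)
    for col in ("pcc_normal", "pcc_tumor"):
        magnitude = table[col].abs().to_numpy()
        cutoff = np.sort(magnitude)[::-1][top - 1]
        selected |= magnitude >= cutoff
    return table[selected].reset_index(drop=True)


def asymmetric_heatmap_matrix(
    genes: Sequence[str], normal: pd.DataFrame, tumor: pd.DataFrame
) -> pd.DataFrame:
    """k x k PCC matrix: lower triangle normal, upper triangle tumor, diagonal 1.

    Row and column order both follow `genes`, so entries mirrored across the
    diagonal describe the same pair under the two conditions.
    """
    genes = list(genes)
    pairs = all_pairs(genes)
    table, rejects = condition_pccs(pairs, normal, tumor)
    if len(rejects):
        raise ValueError(
            f"zero-variance genes break the heatmap grid: {rejects.to_numpy()[:5]}"
        )
    k = len(genes)
    pos = {g: i for i, g in enumerate(genes)}
    out = np.eye(k)
    for row in table.itertuples(index=False):
        i, j = pos[row.gene_a], pos[row.gene_b]
        lo, hi = (i, j) if i > j else (j, i)
        out[lo, hi] = row.pcc_normal  # row index > column index: normal
        out[hi, lo] = row.pcc_tumor
    return pd.DataFrame(out, index=genes, columns=genes)


def landscape_summary(table: pd.DataFrame) -> dict:
    strengthened, weakened = strength_fractions(table)
    slope, intercept = fit_cross_condition_slope(table)
    return {
        "n_pairs": int(len(table)),
        "fraction_strengthened": strengthened,
        "fraction_weakened": weakened,
        "slope": slope,
        "intercept": intercept,
    }
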