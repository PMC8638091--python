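"""DE ranking of genes and preranked enrichment of DCG sets.

Genes are ranked by a signed differential-expression score,
sign(mean tumor - mean normal) * (-log10 p) from a paired (or Welch)
t-test, and a gene set of interest (typically the differentially
coexpressed genes) is tested for nonrandom placement in that ranking with
the weighted Kolmogorov-Smirnov running-sum statistic and a gene-label
permutation p-value. Enrichment is two-sided on |ES| since a DCG set could
concentrate at either extreme of the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .pairs import DEGENERATE_P


def rank_genes_by_de(
    normal: pd.DataFrame, tumor: pd.DataFrame, paired: bool = True
) -> pd.DataFrame:
    """Rank genes by signed -log10 differential-expression p-value.

    With `paired=True` columns of the two matrices are matched positionally
    (subject order) and a paired t-test is used; otherwise Welch's t-test.
    Zero-variance situations get the degenerate smallest-p rule when the
    means differ (flagged), p = 1 when they do not. Ties in score break by
    gene id for a deterministic ranking.
    """
    common = normal.index.intersection(tumor.index)
    a = normal.loc[common].to_numpy(dtype=float)
    b = tumor.loc[common].to_numpy(dtype=float)
    if a.shape[1] < 3 or b.shape[1] < 3:
        raise ValueError("DE ranking needs at least 3 samples per condition")
    if paired:
        if a.shape[1] != b.shape[1]:
            raise ValueError("paired DE ranking needs equal sample counts")
        res = stats.ttest_rel(b, a, axis=1)
    else:
        res = stats.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    mean_diff = b.mean(axis=1) - a.mean(axis=1)
    degenerate = ~np.isfinite(p)
    p[degenerate & (mean_diff != 0)] = DEGENERATE_P
    p[degenerate & (mean_diff == 0)] = 1.0
    score = np.sign(mean_diff) * (-np.log10(p))
    out = pd.DataFrame(
        {"gene_id": common, "score": score, "p": p, "degenerate": degenerate}
    )
    out = out.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def _validate_set(ranked: pd.DataFrame, gene_set: Iterable[str]) -> np.ndarray:
    members = set(gene_set)
    unknown = members - set(ranked["gene_id"])
    if unknown:
        raise ValueError(f"gene set members absent from ranking: {sorted(unknown)[:10]}")
    hits = ranked["gene_id"].isin(members).to_numpy()
    if hits.all() or not hits.any():
        raise ValueError("enrichment score undefined for an empty or full gene set")
    return hits


def _es_from_hits(scores: np.ndarray, hits: np.ndarray, weight: float) -> float:
    if weight == 0:
        increments = np.ones(int(hits.sum()))
    else:
        increments = np.abs(scores[hits]) ** weight
    total = increments.sum()
    if total == 0:  # all hit scores exactly 0: fall back to unweighted steps
        increments = np.ones(int(hits.sum()))
        total = increments.sum()
    step = np.zeros(scores.size)
    step[hits] = increments / total
    step[~hits] = -1.0 / (scores.size - int(hits.sum()))
    running = np.cumsum(step)
    return float(running[np.argmax(np.abs(running))])


def enrichment_score(
    ranked: pd.DataFrame, gene_set: Iterable[str], weight: float = 1.0
) -> float:
    """Signed maximum deviation of the weighted KS running sum.

    Walking down the ranking, a hit advances the running sum by
    |score|^weight (normalized over the set), a miss retreats it by
    1/(G - set size); the ES is the running-sum value of largest magnitude.
    weight=0 recovers the classic Kolmogorov-Smirnov statistic.
    """
    hits = _validate_set(ranked, gene_set)
    return _es_from_hits(ranked["score"].to_numpy(dtype=float), hits, weight)


@dataclass(frozen=True)
class EnrichmentResult:
    es: float
    p: float
    n_perm: int
    set_size: int


def permutation_pvalue(
    ranked: pd.DataFrame,
    gene_set: Iterable[str],
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> EnrichmentResult:
    """Gene-label permutation p-value for the enrichment score.

    p = (1 + #{random same-size sets with |ES*| >= |ES|}) / (n_perm + 1);
    the +1 keeps the estimate strictly positive, so p >= 1/(n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    hits = _validate_set(ranked, gene_set)
    scores = ranked["score"].to_numpy(dtype=float)
    observed = _es_from_hits(scores, hits, weight)
    size = int(hits.sum())
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        idx = rng.choice(scores.size, size=size, replace=False)
        perm_hits = np.zeros(scores.size, dtype=bool)
        perm_hits[idx] = True
        if abs(_es_from_hits(scores, perm_hits, weight)) >= abs(observed):
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return EnrichmentResult(es=observed, p=p, n_perm=n_perm, set_size=size)


def write_rnk(ranked: pd.DataFrame, path: str) -> None:
    """Two-column tab-separated (gene, score) ranking, best score first."""
    ranked[["gene_id", "score"]].to_csv(path, sep="\t", index=False, header=False)
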