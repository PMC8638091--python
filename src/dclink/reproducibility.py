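"""Fold-based reproducibility of correlations and DC calls.

The tumor cohort is split into k folds; each fold is matched against the
same normal set and the regression-form CILP screen is repeated, so every
reference DCL (from one run on the paired samples) earns a recurrence count
in [0, k]. Cross-fold concordance of the per-pair PCC vectors measures how
stable the raw correlation estimates are across tumor subsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import pairs as pc

Pair = tuple[str, str]


@dataclass
class FoldAssignment:
    assignment: pd.Series  # sample_id -> fold index in 1..k
    fold_sizes: list[int]

    def fold(self, index: int) -> list[str]:
        return self.assignment.index[self.assignment == index].tolist()


def split_folds(
    sample_ids: Sequence[str],
    k: int,
    target_size: int | None = None,
    seed: int = 0,
) -> FoldAssignment:
    """Randomly partition samples into k folds.

    With `target_size`, folds 1..k-1 get exactly that many samples and fold
    k takes the remainder (which must be at least 1); otherwise sizes differ
    by at most 1. The permutation is drawn from a generator seeded with
    `seed`, so the split is reproducible.
    """
    ids = list(sample_ids)
    n = len(ids)
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > n:
        raise ValueError(f"cannot split {n} samples into {k} nonempty folds")
    if target_size is not None:
        if target_size * (k - 1) >= n:
            raise ValueError(
                f"infeasible split: {k - 1} folds of {target_size} exhaust {n} samples"
            )
        sizes = [target_size] * (k - 1) + [n - target_size * (k - 1)]
    else:
        base, extra = divmod(n, k)
        sizes = [base + (1 if i < extra else 0) for i in range(k)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    start = 0
    for i, size in enumerate(sizes, start=1):
        folds[order[start : start + size]] = i
        start += size
    return FoldAssignment(
        assignment=pd.Series(folds, index=pd.Index(ids, name="sample_id"), name="fold"),
        fold_sizes=sizes,
    )


def recurrence_counts(
    reference_dcls: pd.DataFrame, run_dcl_sets: Sequence[set[Pair]]
) -> pd.DataFrame:
    """Times each reference DCL reappears across the repeated runs.

    `reference_dcls` needs gene_a/gene_b columns; any stratum columns
    (de_dependence, sign_pattern) are carried through for Fig-2-style
    histograms. Counts lie in [0, len(run_dcl_sets)].
    """
    out = reference_dcls.reset_index(drop=True).copy()
    counts = [
        sum((a, b) in run for run in run_dcl_sets)
        for a, b in zip(out["gene_a"], out["gene_b"])
    ]
    out["recurrence"] = counts
    return out


def recurrence_histogram(recurrence: pd.DataFrame, k: int) -> pd.DataFrame:
    """Recurrence distribution per (de_dependence, sign_pattern) stratum."""
    strata = [c for c in ("de_dependence", "sign_pattern") if c in recurrence.columns]
    grouped = recurrence.groupby(strata + ["recurrence"], observed=True).size()
    hist = grouped.rename("n_pairs").reset_index()
    return hist[hist["recurrence"].between(0, k)]


def cross_fold_pcc_concordance(pcc_vectors: Sequence[np.ndarray]) -> np.ndarray:
    """k x k Pearson correlation matrix between per-fold PCC vectors.

    All vectors must be aligned on the same pair list (equal lengths).
    """
    lengths = {len(v) for v in pcc_vectors}
    if len(lengths) != 1:
        raise ValueError(f"fold PCC vectors are misaligned: lengths {sorted(lengths)}")
    return np.corrcoef(np.vstack(pcc_vectors))


def run_fold_analysis(
    normal: pd.DataFrame,
    tumor: pd.DataFrame,
    pairs: pd.DataFrame,
    k: int = 10,
    target_size: int | None = None,
    fdr_cutoff: float = 0.1,
    de_dependence_fdr: float = 0.1,
    seed: int = 0,
    paired_tumor_samples: Sequence[str] | None = None,
) -> dict:
    """Reference regression-CILP run plus k fold-restricted repeats.

    The reference DCL set comes from one covariate-adjusted run comparing
    `normal` against the paired tumor samples (`paired_tumor_samples`,
    defaulting to the first n_normal tumor columns); repeated runs compare
    each tumor fold against the same normal matrix with the non-paired
    regression test. Returns the fold assignment, reference results,
    per-fold DCL sets, recurrence table and the cross-fold PCC concordance
    matrix.
    """
    if paired_tumor_samples is None:
        paired_tumor_samples = list(tumor.columns[: normal.shape[1]])
    assignment = split_folds(list(tumor.columns), k, target_size=target_size, seed=seed)
    reference, _ = pc.cilp_screen_regression(
        normal,
        tumor[list(paired_tumor_samples)],
        pairs,
        fdr_cutoff=fdr_cutoff,
        de_dependence_fdr=de_dependence_fdr,
    )
    reference_dcls = pc.call_dcls(reference, fdr_cutoff)

    run_sets: list[set[Pair]] = []
    fold_pccs: list[np.ndarray] = []
    for i in range(1, k + 1):
        fold_cols = assignment.fold(i)
        results, _ = pc.cilp_screen_regression(
            normal, tumor[fold_cols], pairs, fdr_cutoff=fdr_cutoff,
            de_dependence_fdr=de_dependence_fdr,
        )
        dcls = pc.call_dcls(results, fdr_cutoff)
        run_sets.append(set(zip(dcls["gene_a"], dcls["gene_b"])))
        fold_pccs.append(results["pcc_tumor"].to_numpy())
    recurrence = recurrence_counts(reference_dcls, run_sets)
    concordance = cross_fold_pcc_concordance(fold_pccs)
    return {
        "fold_assignment": assignment,
        "reference": reference,
        "reference_dcls": reference_dcls,
        "run_dcl_sets": run_sets,
        "recurrence": recurrence,
        "concordance": concordance,
    }
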