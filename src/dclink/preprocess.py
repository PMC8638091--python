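"""Expression preprocessing: log transformation and quantile normalization.

Both steps operate on a genes x samples DataFrame and are applied within a
homogeneous sample group (e.g. the tumor samples of one cohort), never across
conditions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def log_transform(m: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(value + pseudocount), shape preserved.

    Raises ValueError if the matrix contains negative values (raw counts or
    intensities are expected) or if the pseudocount is not positive.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    values = m.to_numpy()
    if (values < 0).any():
        raise ValueError("log_transform requires nonnegative expression values")
    return pd.DataFrame(np.log2(values + pseudocount), index=m.index, columns=m.columns)


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the mean order-statistic distribution.

    After normalization each column holds the same multiset of values (the
    across-column means of the sorted columns) while within-column ranks are
    preserved. Ties within a column receive the mean of the tied target
    quantiles. A single-sample matrix is returned unchanged with a warning.
    """
    if m.shape[1] < 2:
        warnings.warn("quantile_normalize: single sample, returning input unchanged")
        return m.copy()
    values = m.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # ties share the mean of their target quantiles
        tied = pd.Series(assigned).groupby(col, sort=False).transform("mean")
        out[:, j] = tied.to_numpy()
    return pd.DataFrame(out, index=m.index, columns=m.columns)
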