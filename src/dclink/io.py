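"""Readers and writers for the pipeline's tab-separated inputs and outputs.

All tables are TSV, UTF-8, '.' decimal, with a mandatory header row.
Expression matrices are genes x samples: first column holds gene identifiers,
remaining column names are sample identifiers.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

METADATA_COLUMNS = ("sample_id", "subject_id", "condition")
SURVIVAL_COLUMNS = ("subject_id", "time", "event")
PAIR_COLUMNS = ("gene_a", "gene_b")

CONDITIONS = ("normal", "tumor")


class TableFormatError(ValueError):
    """A TSV input violates the declared schema."""


def _check_unique(values: pd.Index | pd.Series, what: str) -> None:
    dup = pd.Index(values)[pd.Index(values).duplicated()].unique()
    if len(dup):
        raise TableFormatError(f"duplicate {what}: {', '.join(map(str, dup[:10]))}")


def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genes x samples expression TSV into a float DataFrame.

    The index holds gene ids, columns hold sample ids. Duplicate gene or
    sample ids and non-numeric cells are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    _check_unique(df.index, "gene id")
    _check_unique(df.columns, "sample id")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
        raise TableFormatError(
            f"non-numeric expression values in columns: {bad[:10]}"
        ) from exc
    if not np.isfinite(df.to_numpy()).all():
        raise TableFormatError("expression matrix contains non-finite values")
    return df


def write_expression(m: pd.DataFrame, path: str | os.PathLike) -> None:
    out = m.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_pairs(path: str | os.PathLike) -> pd.DataFrame:
    """Read a two-column gene-pair list (columns gene_a, gene_b)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"pair list missing columns: {missing}")
    df = df[list(PAIR_COLUMNS)]
    if df.isna().any().any():
        rows = (df.isna().any(axis=1)).to_numpy().nonzero()[0] + 2  # +2: header + 1-based
        raise TableFormatError(f"pair list has empty cells at lines {rows[:10].tolist()}")
    same = df["gene_a"] == df["gene_b"]
    if same.any():
        raise TableFormatError(
            f"self-pairs not allowed: {df.loc[same, 'gene_a'].tolist()[:10]}"
        )
    return df.reset_index(drop=True)


def write_pairs(pairs: pd.DataFrame, path: str | os.PathLike) -> None:
    pairs[list(PAIR_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    """Read the sample table (sample_id, subject_id, condition)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"metadata missing columns: {missing}")
    _check_unique(df["sample_id"], "sample id")
    bad = sorted(set(df["condition"]) - set(CONDITIONS))
    if bad:
        raise TableFormatError(
            f"condition must be one of {CONDITIONS}; found {bad}"
        )
    return df[list(METADATA_COLUMNS)].reset_index(drop=True)


def write_metadata(metadata: pd.DataFrame, path: str | os.PathLike) -> None:
    metadata[list(METADATA_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_survival(path: str | os.PathLike) -> pd.DataFrame:
    """Read the clinical table (subject_id, overall-survival time, event flag)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"survival table missing columns: {missing}")
    df = df[list(SURVIVAL_COLUMNS)]
    _check_unique(df["subject_id"], "subject id")
    df["time"] = pd.to_numeric(df["time"], errors="raise")
    df["event"] = pd.to_numeric(df["event"], errors="raise").astype(int)
    neg = df["time"] < 0
    if neg.any():
        raise TableFormatError(
            f"negative survival time for subjects {df.loc[neg, 'subject_id'].tolist()[:10]}"
        )
    if not df["event"].isin((0, 1)).all():
        raise TableFormatError("event indicator must be 0 (censored) or 1 (death)")
    return df.reset_index(drop=True)


def write_survival(survival: pd.DataFrame, path: str | os.PathLike) -> None:
    survival[list(SURVIVAL_COLUMNS)].to_csv(path, sep="\t", index=False)


def pairing_from_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Derive the subject pairing table from sample metadata.

    Returns one row per subject contributing exactly one normal and one tumor
    sample, with columns subject_id, normal_sample, tumor_sample.
    """
    wide = {}
    for cond in CONDITIONS:
        sub = metadata[metadata["condition"] == cond]
        counts = sub["subject_id"].value_counts()
        multi = counts[counts > 1]
        if len(multi):
            raise TableFormatError(
                f"subjects with multiple {cond} samples: {multi.index.tolist()[:10]}"
            )
        wide[cond] = sub.set_index("subject_id")["sample_id"]
    paired = pd.DataFrame(
        {"normal_sample": wide["normal"], "tumor_sample": wide["tumor"]}
    ).dropna()
    paired.index.name = "subject_id"
    return paired.reset_index()


def check_genes_present(gene_ids: Iterable[str], m: pd.DataFrame, label: str) -> None:
    missing = sorted(set(gene_ids) - set(m.index))
    if missing:
        raise KeyError(f"genes absent from {label} matrix: {missing[:10]}")
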