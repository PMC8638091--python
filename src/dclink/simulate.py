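"""Synthetic paired normal/tumor cohorts with planted coexpression structure.

The generator emulates the statistical skeleton the analysis assumes:
log-scale expression that is Gaussian within each condition, gene pairs with
condition-specific population correlations (planted differential
coexpression), genes with a mean shift in tumor (planted differential
expression), and overall-survival times whose hazard depends on a pair's
sample-wise product correlation through a median dichotomy. It makes no
attempt at negative-binomial count noise, library-size effects or batch
structure.

One integer seed drives a single ``numpy.random.Generator``; every stochastic
helper takes the generator and never reseeds internally, so a cohort is
byte-reproducible from its config.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as dio

Pair = tuple[str, str]


def gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


@dataclass
class SimConfig:
    """Study-condition parameters for one synthetic cohort.

    planted_dc_pairs: (gene_a, gene_b, rho_normal, rho_tumor) tuples; each
        gene may appear in at most one planted pair.
    planted_de_genes: (gene, log2 fold change added in tumor).
    null_pairs: count of background pairs drawn among unplanted genes, with
        rho_normal = rho_tumor = 0.
    prognosis_pairs: ((gene_a, gene_b), hazard_ratio) — subjects whose
        product correlation for the pair exceeds the cohort median carry
        hazard_ratio times the baseline hazard.
    baseline_hazard: event rate per time unit (days) in the low stratum.
    censor_rate: target probability of censoring in the baseline stratum.
    noise_sd: SD of log-scale expression around its mean.
    """

    n_subjects: int = 60
    n_extra_tumor: int = 200
    n_genes: int = 100
    planted_dc_pairs: Sequence[tuple[str, str, float, float]] = field(
        default_factory=list
    )
    planted_de_genes: Sequence[tuple[str, float]] = field(default_factory=list)
    null_pairs: int = 50
    prognosis_pairs: Sequence[tuple[Pair, float]] = field(default_factory=list)
    baseline_hazard: float = 1.0 / 1500.0
    censor_rate: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("need at least 3 paired subjects")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.baseline_hazard <= 0 or self.noise_sd <= 0:
            raise ValueError("baseline_hazard and noise_sd must be positive")
        genes = set(gene_ids(self.n_genes))
        seen: set[str] = set()
        for a, b, rn, rt in self.planted_dc_pairs:
            if max(abs(rn), abs(rt)) >= 1:
                raise ValueError(f"|rho| must be < 1 for pair ({a}, {b})")
            if a == b:
                raise ValueError(f"planted pair genes must be distinct: {a}")
            for g in (a, b):
                if g not in genes:
                    raise ValueError(f"planted gene {g} not among the {self.n_genes} genes")
                if g in seen:
                    raise ValueError(f"gene {g} appears in more than one planted pair")
                seen.add(g)
        for g, _ in self.planted_de_genes:
            if g not in genes:
                raise ValueError(f"DE gene {g} not among the {self.n_genes} genes")
        for (a, b), hr in self.prognosis_pairs:
            if hr <= 0:
                raise ValueError(f"hazard_ratio must be positive for pair ({a}, {b})")
            if a not in genes or b not in genes:
                raise ValueError(f"prognosis pair ({a}, {b}) references unknown genes")


@dataclass
class SyntheticCohort:
    expr_normal: pd.DataFrame
    expr_tumor: pd.DataFrame
    metadata: pd.DataFrame
    survival: pd.DataFrame
    pairs: pd.DataFrame
    truth_dc_pairs: pd.DataFrame
    truth_de_genes: pd.DataFrame
    truth_prognosis_pairs: pd.DataFrame

    @property
    def expression(self) -> pd.DataFrame:
        """Single genes x samples matrix spanning both conditions."""
        return pd.concat([self.expr_normal, self.expr_tumor], axis=1)


def sample_pair_expression(
    rho: float, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw two length-n profiles from a bivariate normal with correlation rho.

    Unit variance, zero mean. Equivalent to multiplying iid standard normals
    by the Cholesky factor of the 2x2 correlation matrix.
    """
    if abs(rho) >= 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    if n < 3:
        raise ValueError(f"need n >= 3 samples, got {n}")
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    y = rho * x + np.sqrt(1.0 - rho * rho) * z
    return x, y


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Simulate one paired normal/tumor cohort from a validated config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = gene_ids(config.n_genes)
    n_norm = config.n_subjects
    n_tum = config.n_subjects + config.n_extra_tumor

    paired_subjects = [f"P{i:04d}" for i in range(1, config.n_subjects + 1)]
    extra_subjects = [f"U{i:04d}" for i in range(1, config.n_extra_tumor + 1)]
    tumor_subjects = paired_subjects + extra_subjects
    normal_samples = [f"{s}-N" for s in paired_subjects]
    tumor_samples = [f"{s}-T" for s in tumor_subjects]

    expr_n = rng.standard_normal((config.n_genes, n_norm)) * config.noise_sd
    expr_t = rng.standard_normal((config.n_genes, n_tum)) * config.noise_sd
    gene_pos = {g: i for i, g in enumerate(genes)}

    for a, b, rho_n, rho_t in config.planted_dc_pairs:
        ia, ib = gene_pos[a], gene_pos[b]
        xa, xb = sample_pair_expression(rho_n, n_norm, rng)
        expr_n[ia], expr_n[ib] = xa * config.noise_sd, xb * config.noise_sd
        xa, xb = sample_pair_expression(rho_t, n_tum, rng)
        expr_t[ia], expr_t[ib] = xa * config.noise_sd, xb * config.noise_sd

    for g, lfc in config.planted_de_genes:
        expr_t[gene_pos[g]] += lfc

    expr_normal = pd.DataFrame(expr_n, index=genes, columns=normal_samples)
    expr_tumor = pd.DataFrame(expr_t, index=genes, columns=tumor_samples)

    # pair list: planted pairs first, then background pairs among spare genes
    planted = [(a, b) for a, b, _, _ in config.planted_dc_pairs]
    used = {g for p in planted for g in p}
    spare = [g for g in genes if g not in used]
    if config.null_pairs > len(spare) * (len(spare) - 1) // 2:
        raise ValueError("not enough unplanted genes for the requested null pairs")
    null: list[Pair] = []
    null_seen: set[frozenset] = set()
    while len(null) < config.null_pairs:
        a, b = rng.choice(len(spare), size=2, replace=False)
        key = frozenset((a, b))
        if key not in null_seen:
            null_seen.add(key)
            null.append((spare[a], spare[b]))
    pairs = pd.DataFrame(planted + null, columns=["gene_a", "gene_b"])

    metadata = pd.DataFrame(
        {
            "sample_id": normal_samples + tumor_samples,
            "subject_id": paired_subjects + tumor_subjects,
            "condition": ["normal"] * n_norm + ["tumor"] * n_tum,
        }
    )

    survival = _simulate_survival(config, expr_tumor, tumor_subjects, rng)

    truth_dc = pd.DataFrame(
        config.planted_dc_pairs, columns=["gene_a", "gene_b", "rho_normal", "rho_tumor"]
    )
    truth_de = pd.DataFrame(config.planted_de_genes, columns=["gene_id", "log2_fc"])
    truth_prog = pd.DataFrame(
        [(a, b, hr) for (a, b), hr in config.prognosis_pairs],
        columns=["gene_a", "gene_b", "hazard_ratio"],
    )
    return SyntheticCohort(
        expr_normal=expr_normal,
        expr_tumor=expr_tumor,
        metadata=metadata,
        survival=survival,
        pairs=pairs,
        truth_dc_pairs=truth_dc,
        truth_de_genes=truth_de,
        truth_prognosis_pairs=truth_prog,
    )


def _simulate_survival(
    config: SimConfig,
    expr_tumor: pd.DataFrame,
    tumor_subjects: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Exponential survival with a dichotomized product-correlation covariate.

    For each prognosis pair the subject's log-hazard gains log(hazard_ratio)
    when the pair's product correlation (z-scored across the tumor cohort)
    exceeds the cohort median. Censoring is an independent exponential with
    rate chosen so the baseline stratum is censored with probability
    ``censor_rate``.
    """
    n = len(tumor_subjects)
    log_hazard = np.full(n, np.log(config.baseline_hazard))
    values = expr_tumor.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    z = (values - mean) / np.where(sd == 0, 1.0, sd)
    pos = {g: i for i, g in enumerate(expr_tumor.index)}
    for (a, b), hr in config.prognosis_pairs:
        prod = z[pos[a]] * z[pos[b]]
        high = prod > np.median(prod)
        log_hazard += np.log(hr) * high
    rate = np.exp(log_hazard)
    event_time = rng.exponential(1.0 / rate)
    if config.censor_rate > 0:
        censor_rate = config.baseline_hazard * config.censor_rate / (1 - config.censor_rate)
        censor_time = rng.exponential(1.0 / censor_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame({"subject_id": tumor_subjects, "time": time, "event": event})


def write_cohort(cohort: SyntheticCohort, outdir: str | os.PathLike) -> dict[str, str]:
    """Write the four pipeline inputs plus truth tables; returns the path map."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "expression": os.path.join(outdir, "expression.tsv"),
        "metadata": os.path.join(outdir, "metadata.tsv"),
        "pairs": os.path.join(outdir, "pairs.tsv"),
        "survival": os.path.join(outdir, "survival.tsv"),
        "truth_dc_pairs": os.path.join(outdir, "truth_dc_pairs.tsv"),
        "truth_de_genes": os.path.join(outdir, "truth_de_genes.tsv"),
        "truth_prognosis_pairs": os.path.join(outdir, "truth_prognosis_pairs.tsv"),
    }
    dio.write_expression(cohort.expression, paths["expression"])
    dio.write_metadata(cohort.metadata, paths["metadata"])
    dio.write_pairs(cohort.pairs, paths["pairs"])
    dio.write_survival(cohort.survival, paths["survival"])
    cohort.truth_dc_pairs.to_csv(paths["truth_dc_pairs"], sep="\t", index=False)
    cohort.truth_de_genes.to_csv(paths["truth_de_genes"], sep="\t", index=False)
    cohort.truth_prognosis_pairs.to_csv(paths["truth_prognosis_pairs"], sep="\t", index=False)
    return paths
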