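"""End-to-end orchestration of the differential-coexpression analysis.

Stage order mirrors the study design: preprocessing within each condition,
correlation-landscape diagnostics over the supplied pair list, the paired
CILP screen that calls DCLs, a covariate-adjusted regression run that labels
DCLs DE-dependent or DE-independent, the survival screen of DCLs on the
non-paired tumor cohort, and finally preranked enrichment of the DCG set in
the differential-expression ranking. Every stage writes its TSV output and
the run closes with a JSON manifest of the configuration and stage counts.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass

import pandas as pd

from . import enrichment as enr
from . import io as dio
from . import landscape as lsc
from . import pairs as pc
from . import preprocess as pp
from . import prognosis as prg

logger = logging.getLogger(__name__)


class InsufficientPairedSamplesError(ValueError):
    """Matched tumor/normal subject count falls below the configured minimum."""


@dataclass
class PipelineConfig:
    expression: str
    metadata: str
    pairs: str
    survival: str | None = None
    outdir: str = "dclink_results"
    dcl_fdr: float = 0.3
    survival_fdr: float = 0.3
    de_dependence_fdr: float = 0.1
    half_threshold_fraction: float = 0.01
    min_matched_pairs: int = 20
    log_transform: bool = False
    pseudocount: float = 1.0
    quantile_normalize: bool = True
    enrichment_permutations: int = 1000
    enrichment_weight: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("dcl_fdr", "survival_fdr", "de_dependence_fdr",
                     "half_threshold_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.min_matched_pairs < 3:
            raise ValueError("min_matched_pairs must be at least 3")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the result bundle.

    The bundle maps stage names to DataFrames (landscape, dc_results, dcls,
    regression_results, prognosis_results, prognosis_dcls, de_ranking) plus
    the manifest dict. All tables and the manifest are also written under
    config.outdir.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)

    expr = dio.read_expression(config.expression)
    metadata = dio.read_metadata(config.metadata)
    pair_list = dio.read_pairs(config.pairs)
    survival = dio.read_survival(config.survival) if config.survival else None

    unknown = sorted(set(metadata["sample_id"]) - set(expr.columns))
    if unknown:
        raise dio.TableFormatError(f"metadata samples missing from expression: {unknown[:10]}")
    by_cond = {
        cond: expr[metadata.loc[metadata["condition"] == cond, "sample_id"]]
        for cond in dio.CONDITIONS
    }
    pairing = dio.pairing_from_metadata(metadata)
    if len(pairing) < config.min_matched_pairs:
        raise InsufficientPairedSamplesError(
            f"only {len(pairing)} matched tumor/normal subjects; "
            f"at least {config.min_matched_pairs} required"
        )

    # --- preprocessing, within each homogeneous group ---
    processed = {}
    for cond, m in by_cond.items():
        if config.log_transform:
            m = pp.log_transform(m, pseudocount=config.pseudocount)
        if config.quantile_normalize:
            m = pp.quantile_normalize(m)
        processed[cond] = m
    normal, tumor = processed["normal"], processed["tumor"]
    paired_normal = normal[pairing["normal_sample"]]
    paired_tumor = tumor[pairing["tumor_sample"]]

    # --- landscape diagnostics over the pair list ---
    landscape_table, landscape_rejects = lsc.condition_pccs(
        pair_list, paired_normal, paired_tumor
    )
    summary = lsc.landscape_summary(landscape_table)

    # --- paired CILP screen: DCL calling ---
    dc_results, dc_rejects = pc.cilp_screen_paired(
        normal, tumor, pair_list, pairing, fdr_cutoff=config.dcl_fdr
    )
    dcls = pc.call_dcls(dc_results, config.dcl_fdr)

    # --- covariate-adjusted regression run: DE-dependence labels for DCLs ---
    regression_results, _ = pc.cilp_screen_regression(
        paired_normal,
        paired_tumor,
        pair_list,
        fdr_cutoff=config.dcl_fdr,
        de_dependence_fdr=config.de_dependence_fdr,
    )
    labels = regression_results[["gene_a", "gene_b", "de_dependence"]]
    dcls = dcls.merge(labels, on=["gene_a", "gene_b"], how="left")

    dcgs = sorted(set(dcls["gene_a"]) | set(dcls["gene_b"]))

    # --- survival screen of DCLs (paired-contributing subjects excluded) ---
    prognosis_results = pd.DataFrame()
    prognosis_dcls = pd.DataFrame()
    if survival is not None and len(dcls):
        sample_to_subject = dict(
            zip(metadata["sample_id"], metadata["subject_id"])
        )
        prognosis_results = prg.screen_prognosis(
            tumor,
            dcls,
            survival,
            sample_to_subject,
            exclude_subjects=pairing["subject_id"].tolist(),
            fdr_cutoff=config.survival_fdr,
        )
        prognosis_dcls = prg.call_prognosis_dcls(prognosis_results, config.survival_fdr)

    # --- DE ranking and DCG enrichment ---
    de_ranking = enr.rank_genes_by_de(paired_normal, paired_tumor, paired=True)
    enrich = None
    if 0 < len(dcgs) < len(de_ranking):
        enrich = enr.permutation_pvalue(
            de_ranking,
            dcgs,
            n_perm=config.enrichment_permutations,
            weight=config.enrichment_weight,
            seed=config.seed,
        )

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "counts": {
            "genes": int(expr.shape[0]),
            "samples_normal": int(by_cond["normal"].shape[1]),
            "samples_tumor": int(by_cond["tumor"].shape[1]),
            "matched_subjects": int(len(pairing)),
            "pairs_listed": int(len(pair_list)),
            "pairs_tested": int(len(dc_results)),
            "pairs_rejected": int(len(dc_rejects) + len(landscape_rejects)),
            "dcls": int(len(dcls)),
            "de_dependent_dcls": int(
                (dcls["de_dependence"] == pc.DE_DEPENDENT).sum()
                if "de_dependence" in dcls
                else 0
            ),
            "de_independent_dcls": int(
                (dcls["de_dependence"] == pc.DE_INDEPENDENT).sum()
                if "de_dependence" in dcls
                else 0
            ),
            "dcgs": len(dcgs),
            "prognosis_dcls": int(len(prognosis_dcls)),
        },
        "landscape": summary,
        "enrichment": (
            {"es": enrich.es, "p": enrich.p, "n_perm": enrich.n_perm,
             "set_size": enrich.set_size}
            if enrich is not None
            else None
        ),
    }

    _write_outputs(
        config.outdir,
        landscape=landscape_table,
        dc_results=dc_results,
        dcls=dcls,
        regression_results=regression_results,
        prognosis_results=prognosis_results,
        prognosis_dcls=prognosis_dcls,
        de_ranking=de_ranking,
        manifest=manifest,
    )
    return {
        "landscape": landscape_table,
        "landscape_summary": summary,
        "dc_results": dc_results,
        "dcls": dcls,
        "regression_results": regression_results,
        "prognosis_results": prognosis_results,
        "prognosis_dcls": prognosis_dcls,
        "de_ranking": de_ranking,
        "dcgs": dcgs,
        "enrichment": enrich,
        "manifest": manifest,
    }


def _write_outputs(outdir: str, manifest: dict, **tables: pd.DataFrame) -> None:
    for name, table in tables.items():
        if isinstance(table, pd.DataFrame):
            table.to_csv(os.path.join(outdir, f"{name}.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
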