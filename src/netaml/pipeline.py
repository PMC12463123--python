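"""End-to-end orchestration of the per-drug signature workflow.

Chains the stages in their canonical order for each drug that survives QC:

    QC -> correlation screen -> pathway retention -> hot modules
       -> connectivity expansion -> feature sets -> model selection
       -> signed per-sample scoring

Each stage draws its seed deterministically from the master seed in the
config, so a full run is a pure function of (inputs, config).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import correlation, models, pathways, qc, scoring
from .config import AnalysisConfig
from .io import (DrugResponseMatrix, ExpressionMatrix, GeneSetCollection,
                 PPINetwork)
from .modules import (DrugModuleSet, assemble_feature_sets,
                      expand_module_set, hot_modules)

logger = logging.getLogger("netaml")

__all__ = ["DrugRun", "PipelineResult", "stage_seed", "run_drug",
           "run_pipeline"]

_STAGE_OFFSETS = {"split": 11, "gsea": 23, "hotnet": 37, "train": 53,
                  "proximity": 71, "simulate": 97}


def stage_seed(master: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return int((master * 1009 + _STAGE_OFFSETS.get(stage, 0)
                + 131 * index) % (2 ** 31))


@dataclass
class DrugRun:
    drug_id: str
    scg_table: pd.DataFrame
    retained_scgs: list[str] = field(default_factory=list)
    enrichments: list = field(default_factory=list)
    heat: dict[str, float] = field(default_factory=dict)
    modules: DrugModuleSet | None = None
    feature_map: dict[str, list[str]] = field(default_factory=dict)
    results: list[models.ModelResult] = field(default_factory=list)
    best: models.TrainedSignatureModel | None = None
    sample_scores: pd.DataFrame | None = None
    score_correlations: dict[str, tuple[float, float]] = \
        field(default_factory=dict)


@dataclass
class PipelineResult:
    qc_report: qc.QCReport
    expr: ExpressionMatrix
    resp: DrugResponseMatrix
    correlations: pd.DataFrame
    drugs: dict[str, DrugRun] = field(default_factory=dict)


def run_drug(drug: str, expr: ExpressionMatrix, resp: DrugResponseMatrix,
             net: PPINetwork, sets: GeneSetCollection,
             corr_table: pd.DataFrame, cfg: AnalysisConfig,
             drug_index: int = 0, train_models: bool = True,
             registry: dict | None = None) -> DrugRun:
    """All drug-specific stages downstream of the correlation screen."""
    tab = corr_table[corr_table["drug"] == drug].copy()
    run = DrugRun(drug_id=drug, scg_table=tab)

    scg_rows = tab[tab["scg_class"] != "none"]
    scgs = list(scg_rows["gene"])
    if not scgs:
        logger.warning("drug %s: no SCG called; skipping", drug)
        return run

    # pathway retention on the signed correlation ranking of all genes
    ranking = tab.dropna(subset=["rho"]).set_index("gene")["rho"]
    run.enrichments = pathways.gsea_preranked(
        ranking, sets, n_perm=cfg.n_permutations,
        seed=stage_seed(cfg.random_seed, "gsea", drug_index))
    run.retained_scgs = pathways.filter_scgs_by_pathways(
        scgs, run.enrichments, sets, p_cutoff=cfg.gsea_p_cutoff)

    signs = {r.gene: ("positive" if r.scg_class == "PCG" else "negative")
             for r in scg_rows.itertuples()}
    zmap = scg_rows.set_index("gene")["z"]
    run.heat = {g: float(abs(zmap[g])) for g in run.retained_scgs
                if g in net.graph and np.isfinite(zmap[g])}

    pre = hot_modules(net, run.heat, cfg, drug_id=drug,
                      seed=stage_seed(cfg.random_seed, "hotnet",
                                      drug_index))
    run.modules = expand_module_set(net, pre, signs, cfg)
    run.feature_map = assemble_feature_sets(run.modules, run.retained_scgs)

    if train_models and run.feature_map:
        seed = stage_seed(cfg.random_seed, "train", drug_index)
        run.results = models.run_scenarios(expr, resp, drug,
                                           run.feature_map, cfg,
                                           registry=registry, seed=seed)
        ok = [r for r in run.results
              if not r.failed and np.isfinite(r.test_auroc)]
        if ok:
            order = list(registry) if registry is not None else \
                list(models.default_registry(seed))
            run.best = models.pick_best(run.results, expr, resp, cfg,
                                        registry_order=order, seed=seed)

    if run.modules and run.modules.modules:
        pos, neg = run.modules.signed_sets(0)
        gene_sets = {}
        if pos:
            gene_sets[f"{drug}_PMG"] = pos
        if neg:
            gene_sets[f"{drug}_NMG"] = neg
        if gene_sets:
            run.sample_scores = scoring.score_cohort(expr, gene_sets)
            for name in gene_sets:
                try:
                    run.score_correlations[name] = \
                        scoring.cohort_enrichment_correlation(
                            run.sample_scores, resp, drug, name)
                except ValueError:
                    pass
    return run


def run_pipeline(expr: ExpressionMatrix, resp: DrugResponseMatrix,
                 net: PPINetwork, sets: GeneSetCollection,
                 cfg: AnalysisConfig, drugs: list[str] | None = None,
                 scg_mode: str = "fixed", train_models: bool = True,
                 registry: dict | None = None) -> PipelineResult:
    """QC, screen, and per-drug signature construction for a cohort."""
    expr_f, resp_f, report = qc.run_qc(expr, resp, cfg)
    corr = correlation.spearman_drug_gene(expr_f, resp_f)
    corr = correlation.classify_scgs(
        corr, mode=scg_mode, z_pos_cutoff=cfg.z_pos_cutoff,
        z_neg_cutoff=cfg.z_neg_cutoff, top_quantile=cfg.scg_top_quantile)
    out = PipelineResult(qc_report=report, expr=expr_f, resp=resp_f,
                         correlations=corr)
    todo = drugs if drugs is not None else list(resp_f.drug_ids)
    for i, drug in enumerate(todo):
        out.drugs[drug] = run_drug(drug, expr_f, resp_f, net, sets, corr,
                                   cfg, drug_index=i,
                                   train_models=train_models,
                                   registry=registry)
    return out
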