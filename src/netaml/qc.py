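"""Cohort quality-control filters.

The ex vivo AUC matrix is cleaned in a fixed order — samples, then drugs,
then genes — using three rules:

* an *extreme-response threshold* is taken as a high quantile (default the
  95th percentile) of the pooled non-missing AUC distribution;
* a **sample** is removed when every one of its measured AUCs strictly
  exceeds that threshold (uniform extremes point at a technical artifact),
  or when it carries no measurements at all;
* a **drug** is removed when strictly more than a set fraction (default 90%)
  of its measured AUCs strictly exceed the threshold (no usable variability),
  or when it was screened in fewer than a minimum number of samples
  (default 35) counted after sample removal;
* a **gene** is kept when its raw count strictly exceeds a floor (default 1)
  in at least ``ceil(fraction * n_samples)`` samples (default 10%).

Fractions are always computed over non-missing entries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import DrugResponseMatrix, ExpressionMatrix

logger = logging.getLogger("netaml")

__all__ = [
    "QCReport", "extreme_auc_threshold", "filter_samples", "filter_drugs",
    "filter_genes", "run_qc",
]

REASON_EXTREME_FRACTION = "extreme_fraction"
REASON_MIN_N = "min_n"
REASON_ALL_EXTREME = "all_extreme"
REASON_NO_DATA = "no_data"
REASON_LOW_EXPRESSION = "low_expression"


@dataclass
class QCReport:
    """Survivors and casualties of each filter, with one reason per drop."""

    extreme_threshold: float = float("nan")
    kept_samples: list[str] = field(default_factory=list)
    dropped_samples: dict[str, str] = field(default_factory=dict)
    kept_drugs: list[str] = field(default_factory=list)
    dropped_drugs: dict[str, str] = field(default_factory=dict)
    kept_genes: list[str] = field(default_factory=list)
    dropped_genes: dict[str, str] = field(default_factory=dict)
    filter_order: tuple[str, ...] = ("samples", "drugs", "genes")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kind, kept, dropped in (
                ("sample", self.kept_samples, self.dropped_samples),
                ("drug", self.kept_drugs, self.dropped_drugs),
                ("gene", self.kept_genes, self.dropped_genes)):
            rows += [(kind, i, "kept", "") for i in kept]
            rows += [(kind, i, "dropped", r) for i, r in dropped.items()]
        return pd.DataFrame(rows, columns=["kind", "id", "status", "reason"])


def extreme_auc_threshold(resp: DrugResponseMatrix, q: float = 0.95) -> float:
    """Quantile of the pooled non-missing AUC distribution.

    Uses the linear-interpolation quantile definition
    (``h = (n - 1) q + 1`` on the order statistics).
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile must lie in (0,1); got {q}")
    pooled = resp.auc.to_numpy(dtype=float).ravel()
    pooled = pooled[~np.isnan(pooled)]
    if pooled.size == 0:
        raise ValueError("all AUC values are missing")
    return float(np.quantile(pooled, q))


def filter_samples(resp: DrugResponseMatrix, threshold: float) -> QCReport:
    """Drop samples whose every measured AUC strictly exceeds ``threshold``."""
    report = QCReport(extreme_threshold=threshold)
    a = resp.auc
    for sample in a.columns:
        col = a[sample].dropna()
        if col.empty:
            report.dropped_samples[sample] = REASON_NO_DATA
        elif (col > threshold).all():
            report.dropped_samples[sample] = REASON_ALL_EXTREME
        else:
            report.kept_samples.append(sample)
    return report


def filter_drugs(resp: DrugResponseMatrix, threshold: float,
                 extreme_fraction: float = 0.90,
                 min_n: int = 35) -> QCReport:
    """Drop drugs with near-uniform extreme response or too few screens.

    A drug falls when strictly more than ``extreme_fraction`` of its
    non-missing AUCs strictly exceed ``threshold``, or when fewer than
    ``min_n`` samples carry a measurement.
    """
    report = QCReport(extreme_threshold=threshold)
    for drug in resp.auc.index:
        row = resp.auc.loc[drug].dropna()
        if len(row) < min_n:
            report.dropped_drugs[drug] = REASON_MIN_N
        elif len(row) and (row > threshold).mean() > extreme_fraction:
            report.dropped_drugs[drug] = REASON_EXTREME_FRACTION
        else:
            report.kept_drugs.append(drug)
    if not report.kept_drugs:
        logger.warning("drug filter removed every drug")
    return report


def filter_genes(expr: ExpressionMatrix, min_count: float = 1.0,
                 min_fraction: float = 0.10) -> QCReport:
    """Keep genes whose raw count exceeds ``min_count`` often enough.

    A gene survives iff the number of samples with count strictly greater
    than ``min_count`` is at least ``ceil(min_fraction * n_samples)``.
    """
    if expr.counts is None:
        raise ValueError(
            "gene filter needs a raw-count layer; load the expression file "
            "with counts=True or skip the gene filter")
    report = QCReport()
    need = math.ceil(min_fraction * expr.counts.shape[1])
    n_pass = (expr.counts > min_count).sum(axis=1)
    for gene, k in n_pass.items():
        if k >= need:
            report.kept_genes.append(gene)
        else:
            report.dropped_genes[gene] = REASON_LOW_EXPRESSION
    return report


def run_qc(expr: ExpressionMatrix, resp: DrugResponseMatrix,
           cfg: AnalysisConfig,
           threshold: float | None = None,
           ) -> tuple[ExpressionMatrix, DrugResponseMatrix, QCReport]:
    """Apply the sample -> drug -> gene filter chain.

    The extreme threshold is computed from the raw pooled AUC distribution
    (before any exclusion) unless supplied. The drug minimum-screen count is
    evaluated after sample removal.
    """
    if threshold is None:
        threshold = extreme_auc_threshold(resp, cfg.extreme_quantile)
    logger.info("extreme AUC threshold (q=%g): %.4f",
                cfg.extreme_quantile, threshold)

    srep = filter_samples(resp, threshold)
    resp1 = resp.subset(samples=srep.kept_samples)

    drep = filter_drugs(resp1, threshold,
                        extreme_fraction=cfg.drug_extreme_fraction,
                        min_n=cfg.min_samples_per_drug)
    resp2 = resp1.subset(drugs=drep.kept_drugs)

    # keep every expression sample that survived the response filter, plus
    # expression-only samples are dropped to keep the cohorts aligned
    expr1 = expr.subset(samples=[s for s in expr.sample_ids
                                 if s in set(srep.kept_samples)])
    if expr.counts is not None:
        grep = filter_genes(expr1, min_count=cfg.gene_min_count,
                            min_fraction=cfg.gene_min_fraction)
        expr2 = expr1.subset(genes=grep.kept_genes)
    else:
        grep = QCReport(kept_genes=list(expr1.gene_ids))
        expr2 = expr1

    report = QCReport(
        extreme_threshold=threshold,
        kept_samples=srep.kept_samples, dropped_samples=srep.dropped_samples,
        kept_drugs=drep.kept_drugs, dropped_drugs=drep.dropped_drugs,
        kept_genes=grep.kept_genes, dropped_genes=grep.dropped_genes)
    logger.info("QC: %d/%d samples, %d/%d drugs, %d/%d genes kept",
                len(report.kept_samples), len(resp.sample_ids),
                len(report.kept_drugs), len(resp.drug_ids),
                len(report.kept_genes), len(expr.gene_ids))
    return expr2, resp2, report
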