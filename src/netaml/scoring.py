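"""Per-sample enrichment of signed module genes.

The positive and negative module genes of a drug (PMGs/NMGs) are treated as
separate gene sets and scored per sample with a rank-weighted running-sum
statistic in the single-sample GSEA tradition: genes are ranked by their
expression within the sample, hits accumulate weight rank^tau (tau = 0.25
by default), misses accumulate uniformly, and the score is the sum of the
difference of the two cumulative distributions over the whole ranking.
With tau = 0 the score is a pure rank statistic, invariant under any
strictly monotone transform of the expression values.

Samples are labeled sensitive/resistant per drug by the median (or mean)
AUC; *lower* AUC means more cell killing, i.e. the sensitive class.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import DrugResponseMatrix, ExpressionMatrix

logger = logging.getLogger("netaml")

__all__ = ["ssgsea_score", "score_cohort", "cohort_enrichment_correlation",
           "classify_sensitivity"]


def ssgsea_score(sample_values: pd.Series, gene_set: list[str],
                 weight: float = 0.25) -> float:
    """Single-sample enrichment score of ``gene_set`` in one sample.

    ``sample_values`` maps every expressed gene to its (normalized)
    expression in the sample. Raises when no set member is expressed.
    """
    values = pd.Series(sample_values, dtype=float).dropna()
    n = len(values)
    members = [g for g in gene_set if g in values.index]
    if not members:
        raise ValueError("no gene-set member in the expressed universe")
    if len(members) == n:
        return 0.0
    # descending expression order; stable sort keeps ties deterministic
    order = values.sort_values(ascending=False, kind="mergesort")
    hit = order.index.isin(members)
    ranks = np.arange(n, 0, -1, dtype=float)      # top gene has rank n
    w = ranks ** weight
    hit_w = np.where(hit, w, 0.0)
    p_hit = np.cumsum(hit_w) / hit_w.sum()
    p_miss = np.cumsum(~hit) / (n - len(members))
    return float(np.sum(p_hit - p_miss))


def score_cohort(expr: ExpressionMatrix,
                 gene_sets: dict[str, list[str]],
                 weight: float = 0.25) -> pd.DataFrame:
    """Long-format per-sample scores for several gene sets.

    Columns: sample, set_name, es. Sets with no expressed member are
    skipped with a warning (flagged missing rather than zero).
    """
    rows = []
    for name, members in gene_sets.items():
        usable = [g for g in members if g in expr.values.index]
        if not usable:
            logger.warning("set %s: no member expressed; scores missing",
                           name)
            continue
        for sample in expr.sample_ids:
            es = ssgsea_score(expr.values[sample], usable, weight)
            rows.append((sample, name, es))
    return pd.DataFrame(rows, columns=["sample", "set_name", "es"])


def cohort_enrichment_correlation(scores: pd.DataFrame,
                                  resp: DrugResponseMatrix, drug: str,
                                  set_name: str) -> tuple[float, float]:
    """Pearson correlation of one set's enrichment scores with a drug's AUC.

    Returns (r, two-sided p) over the paired samples; requires at least 3
    pairs and non-constant vectors.
    """
    es = (scores[scores["set_name"] == set_name]
          .set_index("sample")["es"])
    auc = resp.auc.loc[drug].dropna()
    common = [s for s in es.index if s in auc.index]
    if len(common) < 3:
        raise ValueError(f"need >= 3 paired samples; got {len(common)}")
    x = es[common].to_numpy(dtype=float)
    y = auc[common].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("constant vector: correlation undefined")
        return float("nan"), float("nan")
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def classify_sensitivity(resp: DrugResponseMatrix, drug: str,
                         rule: str = "median") -> pd.Series:
    """Label each measured sample 'sensitive' or 'resistant' for one drug.

    The threshold is the per-drug median (default) or mean AUC; samples at
    or below the threshold are sensitive (lower AUC = stronger response).
    """
    auc = resp.auc.loc[drug].dropna()
    if len(auc) < 2:
        raise ValueError("need >= 2 measured samples to classify")
    if rule == "median":
        threshold = float(auc.median())
    elif rule == "mean":
        threshold = float(auc.mean())
    else:
        raise ValueError(f"rule must be 'median' or 'mean'; got {rule!r}")
    labels = pd.Series(np.where(auc <= threshold, "sensitive", "resistant"),
                       index=auc.index, name=drug)
    if auc.nunique() == 1:
        logger.warning("drug %s: constant AUC; all samples sensitive", drug)
    return labels
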