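"""Pathway-level filtering of correlated genes.

Candidate genes for each drug are ranked by their signed correlation with
the drug's AUC and tested for pathway enrichment with a pre-ranked,
weighted Kolmogorov-Smirnov running-sum statistic (the GSEA enrichment
score, weight exponent 1 on the absolute ranking score). Significance comes
from a seeded gene-label permutation null. Correlated genes that belong to
at least one enriched pathway are retained as module seeds; when nothing is
enriched the gene list passes through unfiltered with a logged flag so a
small cohort cannot dead-end the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneSetCollection

logger = logging.getLogger("netaml")

__all__ = ["EnrichmentResult", "gsea_preranked", "filter_scgs_by_pathways"]


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p: float
    leading_edge: list[str] = field(default_factory=list)
    n_members: int = 0


def _running_sum_es(order_scores: np.ndarray, hit_mask: np.ndarray,
                    weight: float) -> tuple[float, int]:
    """Signed max-deviation enrichment score and its peak index.

    ``order_scores`` are the ranking scores already sorted descending;
    ``hit_mask`` flags set members in that order.
    """
    n = order_scores.size
    n_hit = int(hit_mask.sum())
    if n_hit == 0 or n_hit == n:
        return 0.0, 0
    w = np.abs(order_scores) ** weight if weight != 0 else \
        np.ones(n)
    hit_w = np.where(hit_mask, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:                       # all member scores exactly zero
        hit_w = hit_mask.astype(float)
        denom = n_hit
    p_hit = np.cumsum(hit_w) / denom
    p_miss = np.cumsum(~hit_mask) / (n - n_hit)
    run = p_hit - p_miss
    peak = int(np.argmax(np.abs(run)))
    return float(run[peak]), peak


def gsea_preranked(ranking: pd.Series | dict, sets: GeneSetCollection,
                   n_perm: int = 1000, seed: int = 0,
                   weight: float = 1.0) -> list[EnrichmentResult]:
    """Pre-ranked enrichment over every gene set in ``sets``.

    Parameters
    ----------
    ranking
        Gene -> signed ranking score (e.g. Spearman rho with AUC).
    n_perm
        Gene-label permutation draws for the null; p-values use the
        add-one rule within same-sign null scores, so p is in (0, 1].
    weight
        Exponent on the absolute ranking score in the running sum
        (1 = classic weighted statistic, 0 = unweighted KS).

    NES is the observed score divided by the mean absolute same-sign null
    score. Sets with fewer than 2 members inside the ranked universe are
    skipped with a warning.
    """
    ranking = pd.Series(ranking, dtype=float).dropna()
    if ranking.index.has_duplicates:
        raise ValueError("duplicate genes in ranking")
    if ranking.nunique() < 2:
        raise ValueError("ranking needs at least 2 distinct scores")
    order = ranking.sort_values(ascending=False, kind="mergesort")
    genes = order.index.to_numpy()
    scores = order.to_numpy()
    pos = {g: i for i, g in enumerate(genes)}
    n = genes.size
    rng = np.random.default_rng(seed)

    results: list[EnrichmentResult] = []
    for name, members in sets.items():
        idx = np.array(sorted(pos[g] for g in members if g in pos),
                       dtype=int)
        if idx.size < 2:
            logger.warning("set %s: <2 members in ranked universe; skipped",
                           name)
            continue
        hit = np.zeros(n, dtype=bool)
        hit[idx] = True
        es, peak = _running_sum_es(scores, hit, weight)
        # leading edge: members up to (resp. after) the running-sum peak
        if es >= 0:
            lead = [genes[i] for i in idx if i <= peak]
        else:
            lead = [genes[i] for i in idx if i >= peak]

        null = np.empty(n_perm)
        k = idx.size
        for b in range(n_perm):
            hb = np.zeros(n, dtype=bool)
            hb[rng.choice(n, size=k, replace=False)] = True
            null[b], _ = _running_sum_es(scores, hb, weight)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if same.size:
            p = (1.0 + np.sum(np.abs(same) >= abs(es))) / (1.0 + same.size)
            scale = np.mean(np.abs(same))
            nes = es / scale if scale > 0 else 0.0
        else:
            p, nes = 1.0 / (1.0 + n_perm), np.nan
        results.append(EnrichmentResult(set_name=name, es=es, nes=nes,
                                        p=float(p), leading_edge=lead,
                                        n_members=int(k)))
    return results


def filter_scgs_by_pathways(scgs: list[str] | pd.Series,
                            results: list[EnrichmentResult],
                            sets: GeneSetCollection,
                            p_cutoff: float = 0.05) -> list[str]:
    """Keep genes that belong to at least one enriched pathway.

    Membership uses the full gene-set definition (not only the leading
    edge), so the output is monotone in ``p_cutoff``: a larger cutoff
    retains a superset. Falls back to the full input list (with a logged
    flag) when no pathway clears the cutoff, so downstream module
    detection still has seeds.
    """
    scgs = list(scgs)
    enriched = {r.set_name for r in results if r.p < p_cutoff}
    if not enriched:
        logger.warning("no pathway enriched at p<%g; passing %d genes "
                       "through unfiltered", p_cutoff, len(scgs))
        return scgs
    members: set[str] = set()
    for name in enriched:
        members.update(sets.members(name))
    return [g for g in scgs if g in members]


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.set_name, r.n_members, r.es, r.nes, r.p,
          ";".join(r.leading_edge)) for r in results],
        columns=["set_name", "n_members", "es", "nes", "p", "leading_edge"])
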