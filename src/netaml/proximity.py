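"""Target-to-signature network proximity.

The closest-distance proximity between a drug's target set T and its
signature gene set G on the protein-interaction network is

    d(T, G) = (1 / |T|) * sum over t in T of  min over g in G of  d(t, g),

where d(t, g) is the unweighted shortest-path length. A drug whose targets
sit inside its own signature has d = 0. Significance comes from a
degree-aware null: random sets matching |T| and |G| are drawn with node
replacement within log2-degree bins, each scored by the same statistic, and

    z = (d - mean(null)) / sd(null),
    p = (1 + #{null <= d}) / (n_draws + 1)

so a negative z with small p says the targets are closer to the signature
than degree-matched chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .config import AnalysisConfig
from .io import PPINetwork

logger = logging.getLogger("netaml")

__all__ = ["ProximityResult", "closest_distance", "proximity_null",
           "proximity_zscore"]


@dataclass
class ProximityResult:
    d: float
    z: float
    p_empirical: float
    null_mean: float
    null_sd: float
    n_null: int
    n_unreachable: int = 0


def _graph_of(net: PPINetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, PPINetwork) else net


def _restrict(g: nx.Graph, genes: list[str], name: str) -> list[str]:
    inside = [v for v in dict.fromkeys(genes) if v in g]
    if not inside:
        lost = sorted(set(genes))
        raise ValueError(f"no {name} gene maps to the network "
                         f"(lost: {lost[:10]}{'...' if len(lost) > 10 else ''})")
    return inside


def closest_distance(net: PPINetwork | nx.Graph, targets: list[str],
                     signatures: list[str],
                     _strict: bool = True) -> tuple[float, int]:
    """Mean over targets of the hop distance to the nearest signature gene.

    Unreachable targets are excluded from the average (their count is
    returned); if every target is unreachable an error is raised.
    A single breadth-first search from the whole signature set gives each
    node its distance to the nearest member.
    """
    g = _graph_of(net)
    if _strict:
        targets = _restrict(g, targets, "target")
        signatures = _restrict(g, signatures, "signature")
    dist = nx.multi_source_dijkstra_path_length(g, set(signatures),
                                                weight=None)
    per_target = [dist[t] for t in targets if t in dist]
    n_unreachable = len(targets) - len(per_target)
    if not per_target:
        raise ValueError("every target is unreachable from the signature")
    if n_unreachable:
        logger.info("%d/%d targets unreachable; excluded from the mean",
                    n_unreachable, len(targets))
    return float(np.mean(per_target)), n_unreachable


def _degree_bins(g: nx.Graph, min_bin: int = 10) -> dict[str, np.ndarray]:
    """Map each node to its log2-degree bin's member array.

    Bins with fewer than ``min_bin`` nodes are merged upward into the
    nearest occupied bin so every draw has enough candidates.
    """
    by_bin: dict[int, list[str]] = {}
    for v, k in g.degree():
        b = int(np.log2(k)) if k > 0 else -1
        by_bin.setdefault(b, []).append(v)
    keys = sorted(by_bin)
    merged: list[list[str]] = []
    pending: list[str] = []
    for b in keys:
        pending += by_bin[b]
        if len(pending) >= min_bin:
            merged.append(pending)
            pending = []
    if pending:
        if merged:
            merged[-1] += pending
        else:
            merged.append(pending)
            logger.warning("degree bins collapsed to one (tiny network)")
    node_to_members: dict[str, np.ndarray] = {}
    for members in merged:
        arr = np.array(sorted(members))
        for v in members:
            node_to_members[v] = arr
    return node_to_members


def proximity_null(net: PPINetwork | nx.Graph, targets: list[str],
                   signatures: list[str], n_draws: int = 1000,
                   seed: int = 0, degree_aware: bool = True) -> np.ndarray:
    """Null sample of d(T, G) for random degree-matched sets.

    Each draw replaces every target and signature gene with a random node
    from its log2-degree bin (uniform over all nodes when
    ``degree_aware=False``); draws are seeded and reproducible.
    """
    g = _graph_of(net)
    targets = _restrict(g, targets, "target")
    signatures = _restrict(g, signatures, "signature")
    rng = np.random.default_rng(seed)
    if degree_aware:
        bins = _degree_bins(g)
        t_pools = [bins[v] for v in targets]
        s_pools = [bins[v] for v in signatures]
    else:
        allnodes = np.array(sorted(g.nodes))
        t_pools = [allnodes] * len(targets)
        s_pools = [allnodes] * len(signatures)
    out = np.empty(n_draws)
    for i in range(n_draws):
        rt = [str(rng.choice(pool)) for pool in t_pools]
        rs = [str(rng.choice(pool)) for pool in s_pools]
        out[i], _ = closest_distance(g, rt, rs, _strict=False)
    return out


def proximity_zscore(net: PPINetwork | nx.Graph, targets: list[str],
                     signatures: list[str], cfg: AnalysisConfig,
                     seed: int | None = None,
                     degree_aware: bool = True) -> ProximityResult:
    """Observed proximity with its standardized score and empirical p.

    ``p_empirical`` is the add-one fraction of null draws at or below the
    observed d (small p = closer than chance). A degenerate null
    (sd = 0) yields z = NaN with a warning; p is still reported.
    """
    if seed is None:
        seed = cfg.random_seed
    d, n_unreach = closest_distance(net, targets, signatures)
    null = proximity_null(net, targets, signatures,
                          n_draws=cfg.proximity_null_draws, seed=seed,
                          degree_aware=degree_aware)
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    if sd == 0:
        logger.warning("null sd = 0; z undefined")
        z = float("nan")
    else:
        z = (d - mu) / sd
    p = (1.0 + int((null <= d).sum())) / (null.size + 1.0)
    return ProximityResult(d=d, z=z, p_empirical=float(p), null_mean=mu,
                           null_sd=sd, n_null=int(null.size),
                           n_unreachable=n_unreach)
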