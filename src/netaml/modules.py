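"""Drug-specific network module detection and expansion.

Three stages turn a drug's sensitivity-correlated genes (SCGs) into network
modules of the protein-interaction graph:

1. **Insulated heat diffusion.** Each SCG receives heat equal to its
   absolute Fisher-Z score (baseline heat 0 elsewhere) and the heat is
   spread with the insulated diffusion kernel

       F = beta * (I - (1 - beta) * W)^-1,

   where W is the column-normalized adjacency and beta in (0,1) is the
   insulation parameter (default 0.5): each column of F is the stationary
   distribution of a random walk with restart from that node, so columns
   sum to one and entries are non-negative.

2. **Hot-module extraction.** The exchanged-heat matrix E = F . diag(h)
   induces a directed graph on edges with E_ij above a data-driven cutoff
   delta, calibrated on random permutations of the heat assignment as the
   smallest cutoff at which permuted heat no longer produces a component of
   the minimum module size. Components are tested against a
   permutation null that reassigns the heat values over network nodes,
   comparing the connectivity strength (minimum internal exchanged heat)
   that a component of the observed size can reach; the
   largest significant component is recorded and removed, and the analysis
   reruns, up to a maximum number of iterations. The whole iterative
   procedure is repeated with independent permutation seeds and only
   modules recovered (Jaccard >= 0.5) in at least ``consensus_cutoff`` runs
   are reported.

3. **Connectivity-significance expansion.** Each reported module is grown
   by iteratively adding the neighboring gene whose links into the module
   are most significant under a hypergeometric model, with links to the
   original seed genes up-weighted by an integer factor alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from math import comb

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .config import AnalysisConfig
from .io import PPINetwork

logger = logging.getLogger("netaml")

__all__ = [
    "DrugModuleSet", "insulated_diffusion_matrix", "hot_modules",
    "diamond_expand", "expand_module_set", "assemble_feature_sets",
]


@dataclass
class DrugModuleSet:
    """Ordered, disjoint network modules for one drug.

    ``modules[0]`` is "module 1", the largest (summed-heat tie-break).
    ``sign_labels`` maps each module gene to "positive"/"negative"
    (inherited from its PCG/NCG class, expansion genes from their seed
    neighbors); ``provenance`` tags each gene "seed" or "diamond".
    """

    drug_id: str
    modules: list[list[str]] = field(default_factory=list)
    sign_labels: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def module_genes(self) -> list[str]:
        return [g for m in self.modules for g in m]

    def signed_sets(self, module_index: int | None = None
                    ) -> tuple[list[str], list[str]]:
        """(positive module genes, negative module genes)."""
        genes = (self.module_genes() if module_index is None
                 else self.modules[module_index])
        pos = [g for g in genes if self.sign_labels.get(g) == "positive"]
        neg = [g for g in genes if self.sign_labels.get(g) == "negative"]
        return pos, neg

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, module in enumerate(self.modules, start=1):
            for g in module:
                rows.append((self.drug_id, k, g,
                             self.sign_labels.get(g, ""),
                             self.provenance.get(g, "")))
        return pd.DataFrame(rows, columns=["drug", "module_index", "gene",
                                           "sign", "provenance"])


def _graph_of(net: PPINetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, PPINetwork) else net


def insulated_diffusion_matrix(net: PPINetwork | nx.Graph, beta: float,
                               nodes: list | None = None) -> pd.DataFrame:
    """Dense diffusion kernel F = beta (I - (1-beta) W)^-1.

    W is the column-normalized adjacency; an isolated node keeps all its
    heat (its column of F is the unit vector on itself). Columns of F sum
    to one and all entries are non-negative for beta in (0, 1).
    """
    if not 0.0 < beta < 1.0:
        raise ValueError(f"beta must lie in (0,1); got {beta}")
    g = _graph_of(net)
    if nodes is None:
        nodes = list(g.nodes)
    n = len(nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    deg = a.sum(axis=0)
    w = np.divide(a, deg, out=np.zeros_like(a), where=deg > 0)
    w[np.arange(n)[deg == 0], np.arange(n)[deg == 0]] = 1.0
    f = beta * np.linalg.inv(np.eye(n) - (1.0 - beta) * w)
    return pd.DataFrame(f, index=nodes, columns=nodes)


def _components_at(e: np.ndarray, delta: float, min_size: int,
                   inclusive: bool = False) -> list[np.ndarray]:
    """Strongly connected components of size >= min_size.

    Edges of the directed exchanged-heat graph run j -> i when
    E_ij = F_ij * h_j strictly exceeds delta (diagonal ignored);
    ``inclusive`` switches to >= for exceedance checks against a
    threshold taken from another matrix's value grid.
    """
    mask = (e >= delta) if inclusive else (e > delta)
    adj = sparse.csr_matrix(mask.T)     # row=source j, col=target i
    n_comp, labels = connected_components(adj, directed=True,
                                          connection="strong")
    sizes = np.bincount(labels, minlength=n_comp)
    return [np.flatnonzero(labels == c)
            for c in np.flatnonzero(sizes >= min_size)]


def _exchanged_heat(f: np.ndarray, heat: np.ndarray) -> np.ndarray:
    e = f * heat[np.newaxis, :]
    np.fill_diagonal(e, 0.0)
    return e


def _min_killing_delta(e: np.ndarray, min_size: int) -> float:
    """Smallest cutoff at which no component of size >= min_size survives.

    The largest strongly connected component can only shrink as the cutoff
    rises (edges are strictly above it), so bisection over the sorted
    positive E values applies. Returns 0 when even the full positive-edge
    graph has no big-enough component. A component of the given size
    survives at every cutoff strictly below the returned value, so the
    value doubles as the component's connectivity strength.
    """
    vals = np.unique(e[e > 0])
    if vals.size == 0 or not _components_at(e, 0.0, min_size):
        return 0.0
    thresholds = np.concatenate(([0.0], vals))
    lo, hi = 0, thresholds.size - 1     # invariant: survives at lo
    if _components_at(e, float(thresholds[hi]), min_size):
        # cannot happen (above the max E value there are no edges)
        return float(thresholds[hi])
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _components_at(e, float(thresholds[mid]), min_size):
            lo = mid
        else:
            hi = mid
    return float(thresholds[hi])


def _calibrated_delta(f: np.ndarray, heat: np.ndarray, min_size: int,
                      rng: np.random.Generator,
                      n_calibration: int = 100) -> float:
    """Data-driven edge cutoff for the exchanged-heat graph.

    The cutoff is the median, over random permutations of the heat
    assignment, of the smallest cutoff at which the permuted heats no
    longer produce a component of the minimum size — i.e. the smallest
    cutoff that silences random heat placement, so any component observed
    above it reflects the actual concentration of heat on the network.
    """
    deltas = np.empty(n_calibration)
    for b in range(n_calibration):
        deltas[b] = _min_killing_delta(
            _exchanged_heat(f, rng.permutation(heat)), min_size)
    return float(np.median(deltas))


def _max_component_size(f: np.ndarray, heat: np.ndarray,
                        delta: float) -> int:
    e = _exchanged_heat(f, heat)
    adj = sparse.csr_matrix((e > delta).T)
    n_comp, labels = connected_components(adj, directed=True,
                                          connection="strong")
    return int(np.bincount(labels, minlength=n_comp).max())


def _hot_modules_once(g: nx.Graph, heat: dict[str, float],
                      cfg: AnalysisConfig,
                      rng: np.random.Generator) -> list[list[str]]:
    """One full iterative run: find, test, remove-largest, repeat."""
    active = list(g.nodes)
    found: list[list[str]] = []
    for _ in range(cfg.max_module_iterations):
        if len(active) < cfg.min_module_size:
            break
        sub = g.subgraph(active)
        f = insulated_diffusion_matrix(sub, cfg.diffusion_beta,
                                       nodes=active).to_numpy()
        h = np.array([heat.get(v, cfg.baseline_heat) for v in active])
        if not (h > 0).any():
            break
        e_obs = _exchanged_heat(f, h)
        delta = _calibrated_delta(f, h, cfg.min_module_size, rng)
        comps = _components_at(e_obs, delta, cfg.min_module_size)
        if not comps:
            break
        comps = sorted(comps, key=lambda c: (-c.size, -h[c].sum()))
        largest = comps[0]
        # permutation null on the connectivity strength at the observed
        # size: a permuted heat assignment is at least as extreme when a
        # component of the observed size holds together at the observed
        # component's strength (its minimum internal exchanged heat)
        strength = _min_killing_delta(e_obs, largest.size)
        exceed = 0
        for b in range(cfg.n_permutations):
            e_perm = _exchanged_heat(f, rng.permutation(h))
            if _components_at(e_perm, strength, largest.size,
                              inclusive=True):
                exceed += 1
        pval = (1.0 + exceed) / (1.0 + cfg.n_permutations)
        if pval > 0.05:
            break
        module = sorted(active[i] for i in largest)
        found.append(module)
        active = [v for v in active if v not in set(module)]
        if largest.size <= cfg.min_module_size:
            break
    return found


def _jaccard(a: set, b: set) -> float:
    u = len(a | b)
    return len(a & b) / u if u else 0.0


def hot_modules(net: PPINetwork | nx.Graph, heat: dict[str, float],
                cfg: AnalysisConfig, drug_id: str = "",
                seed: int | None = None) -> DrugModuleSet:
    """Consensus hot-module detection for one drug.

    ``heat`` maps seed genes (SCGs) to non-negative scores, conventionally
    the absolute Fisher Z of the drug-gene correlation; nodes outside the
    mapping receive the configured baseline heat (0 by default, so unscored
    genes cannot seed a module). The iterative extract-and-remove procedure
    is run ``consensus_cutoff`` times with independent permutation seeds;
    a module is reported when each run contains a Jaccard >= 0.5 match.
    """
    g = _graph_of(net)
    heat = {k: v for k, v in heat.items() if k in g}
    if any(v < 0 for v in heat.values()):
        raise ValueError("heat values must be non-negative")
    if not heat:
        logger.warning("drug %s: no seed gene maps to the network", drug_id)
        return DrugModuleSet(drug_id=drug_id)
    if seed is None:
        seed = cfg.random_seed
    ss = np.random.SeedSequence(seed)
    n_runs = max(cfg.consensus_cutoff, 1)
    runs = [_hot_modules_once(g, heat, cfg, np.random.default_rng(child))
            for child in ss.spawn(n_runs)]

    consensus: list[list[str]] = []
    for module in runs[0]:
        mset = set(module)
        support = sum(
            1 for run in runs
            if any(_jaccard(mset, set(other)) >= 0.5 for other in run))
        if support >= cfg.consensus_cutoff:
            consensus.append(module)

    def heat_sum(m: list[str]) -> float:
        return sum(heat.get(v, 0.0) for v in m)

    consensus.sort(key=lambda m: (-len(m), -heat_sum(m)))
    return DrugModuleSet(
        drug_id=drug_id, modules=consensus,
        provenance={v: "seed" for m in consensus for v in m})


def _hypergeom_tail(k_min: int, n_pop: int, n_success: int,
                    n_draw: int) -> float:
    """P[X >= k_min] for X ~ Hypergeom(n_pop, n_success, n_draw)."""
    lo = max(k_min, 0, n_draw - (n_pop - n_success))
    hi = min(n_success, n_draw)
    if lo > hi:
        return 0.0
    num = sum(comb(n_success, i) * comb(n_pop - n_success, n_draw - i)
              for i in range(lo, hi + 1))
    return num / comb(n_pop, n_draw)


def diamond_expand(net: PPINetwork | nx.Graph, seeds: list[str],
                   max_added: int = 200, alpha: int = 10) -> list[str]:
    """Iterative expansion by hypergeometric connectivity significance.

    At each step, every node adjacent to the current module is scored by
    the tail probability of drawing at least its number of module links
    when links to the original seeds count ``alpha`` times:

        ks' = alpha * ks + k_ns        (weighted links into the module)
        k'  = k + (alpha - 1) * ks     (weighted degree)
        s'  = alpha * s0 + s_added     (weighted module size)
        N'  = N + (alpha - 1) * s0     (weighted network size)
        p   = P[Hypergeom(N', s', k') >= ks']

    The smallest-p candidate joins the module; ties break toward larger
    total degree, then lexicographically smaller gene id. Tail
    probabilities are computed in exact integer arithmetic (one final
    correctly-rounded division), so ties are decided on the true values.
    Returns the added genes in addition order (seeds excluded).
    """
    g = _graph_of(net)
    seeds = [s for s in seeds if s in g]
    if not seeds:
        raise ValueError("empty seed list (no seed maps to the network)")
    if max_added < 1:
        raise ValueError("max_added must be >= 1")
    seed_set = set(seeds)
    module = set(seeds)
    added: list[str] = []
    n_nodes = g.number_of_nodes()
    s0 = len(seeds)
    n_eff = n_nodes + (alpha - 1) * s0

    candidates = {v for s in module for v in g.neighbors(s)} - module
    while len(added) < max_added and candidates:
        s_eff = alpha * s0 + len(added)
        best = None
        for v in sorted(candidates):
            ks = sum(1 for u in g.neighbors(v) if u in seed_set)
            kns = sum(1 for u in g.neighbors(v)
                      if u in module and u not in seed_set)
            k = g.degree(v)
            ks_eff = alpha * ks + kns
            k_eff = k + (alpha - 1) * ks
            p = _hypergeom_tail(ks_eff, n_eff, s_eff, k_eff)
            key = (p, -k, v)
            if best is None or key < best[0]:
                best = (key, v)
        v = best[1]
        added.append(v)
        module.add(v)
        candidates.discard(v)
        candidates.update(u for u in g.neighbors(v) if u not in module)
    return added


def expand_module_set(net: PPINetwork | nx.Graph, modset: DrugModuleSet,
                      scg_signs: dict[str, str], cfg: AnalysisConfig,
                      expand_raw_seeds: bool = False,
                      raw_seeds: list[str] | None = None) -> DrugModuleSet:
    """Grow each module by connectivity significance and label the result.

    ``scg_signs`` maps SCGs to "positive"/"negative" (from PCG/NCG class);
    expansion genes inherit the majority sign of their seed neighbors
    (ties resolve to "positive"). With ``expand_raw_seeds`` the expansion
    runs once from ``raw_seeds`` instead of per detected module, and its
    additions are appended to module 1.
    """
    g = _graph_of(net)
    out = DrugModuleSet(drug_id=modset.drug_id)
    taken: set[str] = set(modset.module_genes())

    def sign_of(v: str, seeds_here: set[str]) -> str:
        votes = [scg_signs[u] for u in g.neighbors(v)
                 if u in seeds_here and u in scg_signs]
        n_pos = sum(1 for s in votes if s == "positive")
        n_neg = len(votes) - n_pos
        return "negative" if n_neg > n_pos else "positive"

    if expand_raw_seeds:
        seeds = raw_seeds if raw_seeds is not None else \
            (modset.modules[0] if modset.modules else [])
        added = diamond_expand(g, list(seeds), cfg.diamond_max_nodes,
                               cfg.diamond_alpha)
        added = [v for v in added if v not in taken]
        base = list(modset.modules[0]) if modset.modules else list(seeds)
        out.modules = [base + added] + [list(m) for m in modset.modules[1:]]
        expansions = {0: (added, set(seeds))}
    else:
        expansions = {}
        out.modules = []
        for k, module in enumerate(modset.modules):
            added = diamond_expand(g, list(module), cfg.diamond_max_nodes,
                                   cfg.diamond_alpha)
            added = [v for v in added if v not in taken]
            taken.update(added)
            out.modules.append(list(module) + added)
            expansions[k] = (added, set(module))

    for k, module in enumerate(modset.modules):
        for v in module:
            out.provenance[v] = "seed"
            if v in scg_signs:
                out.sign_labels[v] = scg_signs[v]
    for k, (added, seeds_here) in expansions.items():
        for v in added:
            out.provenance[v] = "diamond"
            out.sign_labels[v] = sign_of(v, seeds_here)
    return out


def assemble_feature_sets(modset: DrugModuleSet,
                          scgs: list[str]) -> dict[str, list[str]]:
    """Feature sets for model selection: SCG, M1, M2, M1plus2.

    M1/M2 are the first/second modules after expansion; M1plus2 is their
    union (order-preserving). M2 and M1plus2 are absent for single-module
    drugs; M1plus2 then never duplicates M1.
    """
    out: dict[str, list[str]] = {"SCG": list(scgs)}
    if modset.modules:
        out["M1"] = list(modset.modules[0])
        if len(modset.modules) > 1:
            out["M2"] = list(modset.modules[1])
            out["M1plus2"] = list(dict.fromkeys(out["M1"] + out["M2"]))
    return out
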