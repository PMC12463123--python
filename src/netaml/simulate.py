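"""Seeded synthetic inputs with the statistical structure the pipeline
assumes.

The generator family builds, from a single seed:

* a scale-free protein-interaction backbone (preferential attachment) with
  planted dense subgraphs whose member lists are recorded;
* a cohort whose expression is Gaussian on a log scale around per-gene
  baselines, where each planted module shares a per-sample latent factor so
  module genes are mutually correlated, and whose per-drug AUC is a
  monotone map of that factor plus noise onto a 0-300 scale with a
  stretched right tail (so the extreme-response QC rule has something to
  bite on). Half of each module's genes load positively and half
  negatively, so both PCG and NCG classes exist by construction;
* gene-set collections containing the planted signed modules plus random
  decoys, so the pathway-retention stage is exercised;
* a catalog of tiny hand-specified fixtures with their expected outputs
  embedded, used by the worked examples throughout the test suite.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import (DrugResponseMatrix, ExpressionMatrix, GeneSetCollection,
                 PPINetwork)

__all__ = ["SyntheticCohort", "simulate_ppi", "simulate_cohort",
           "planted_proximity_instance", "toy_fixture"]


@dataclass
class SyntheticCohort:
    expr: ExpressionMatrix
    resp: DrugResponseMatrix
    net: PPINetwork
    sets: GeneSetCollection
    truth: dict[str, dict] = field(default_factory=dict)
    planted_cliques: list[list[str]] = field(default_factory=list)


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def simulate_ppi(n_nodes: int, attachment: int = 3,
                 planted_cliques: tuple[int, ...] = (),
                 seed: int = 0) -> tuple[PPINetwork, list[list[str]]]:
    """Preferential-attachment network with planted cliques.

    Returns the network (edge confidences uniform in (700, 1000], i.e.
    everything above the default high-confidence cutoff) and the recorded
    member lists of the planted cliques (mutually disjoint).
    """
    if n_nodes < 10:
        raise ValueError("n_nodes must be >= 10")
    if sum(planted_cliques) > n_nodes:
        raise ValueError("planted cliques exceed the node budget")
    rng = np.random.default_rng(seed)
    g0 = nx.barabasi_albert_graph(n_nodes, attachment,
                                  seed=int(rng.integers(2 ** 31)))
    mapping = {i: _gene_name(i) for i in g0.nodes}
    g = nx.relabel_nodes(g0, mapping)

    cliques: list[list[str]] = []
    free = list(g.nodes)
    for size in planted_cliques:
        if size > len(free):
            raise ValueError("clique size exceeds remaining nodes")
        members = sorted(
            str(v) for v in rng.choice(free, size=size, replace=False))
        free = [v for v in free if v not in set(members)]
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                g.add_edge(a, b)
        cliques.append(members)

    for a, b in g.edges:
        conf = float(rng.uniform(700.0, 1000.0))
        conf = np.nextafter(conf, 1001.0) if conf == 700.0 else conf
        g[a][b]["confidence"] = conf
        g[a][b]["weight"] = conf / 1000.0
    return PPINetwork(graph=g, confidence_cutoff=700.0), cliques


def _auc_transform(raw: np.ndarray, auc_scale: float) -> np.ndarray:
    """Monotone map of a standardized signal onto [0, auc_scale].

    The bulk maps linearly through the Gaussian CDF; the top 5% is
    stretched toward the scale ceiling so the pooled distribution carries
    the right-tail extremes the QC threshold rule expects.
    """
    z = (raw - raw.mean()) / (raw.std() or 1.0)
    u = stats.norm.cdf(z)
    auc = np.where(u < 0.95,
                   0.8 * u,
                   0.76 + (u - 0.95) * 4.8)
    return auc * auc_scale


def simulate_cohort(net: PPINetwork, planted_cliques: list[list[str]],
                    n_samples: int = 200, n_drugs: int = 5,
                    module_size: int = 30, effect_rho: float = 0.5,
                    noise_sd: float = 0.5, missing_frac: float = 0.10,
                    auc_scale: float = 300.0,
                    seed: int = 0) -> SyntheticCohort:
    """Cohort with planted drug-response modules.

    Each drug is assigned a planted clique; the first ``module_size``
    clique members load on a shared per-sample latent factor (half with
    positive sign, half negative) and the drug's AUC is a monotone map of
    that factor plus Gaussian noise of sd ``noise_sd`` (in units of the
    factor's sd). The loading is chosen so the marginal gene-AUC Spearman
    correlation is approximately ``effect_rho`` in absolute value.
    Missing AUC measurements are dropped uniformly at rate
    ``missing_frac``. The returned truth table records, per drug, the
    planted genes, their signed loadings, the noise sd and the missing
    mask; the gene-set collection contains the signed planted sets plus
    random decoys.
    """
    if not planted_cliques:
        raise ValueError("need at least one planted clique")
    if module_size > min(len(c) for c in planted_cliques):
        raise ValueError("module_size exceeds the smallest planted clique")
    rng = np.random.default_rng(seed)
    genes = sorted(net.graph.nodes)
    samples = [f"S{i:04d}" for i in range(n_samples)]

    lam = min(effect_rho * np.sqrt(1.0 + noise_sd ** 2), 0.99)
    baseline = rng.uniform(2.0, 8.0, size=len(genes))
    values = baseline[:, None] + rng.normal(size=(len(genes), n_samples))
    gi = {g: i for i, g in enumerate(genes)}

    factors = {}
    for c, members in enumerate(planted_cliques):
        f = rng.normal(size=n_samples)
        factors[c] = f
        module = members[:module_size]
        for j, g in enumerate(module):
            sign = 1.0 if j < module_size // 2 else -1.0
            values[gi[g]] = (baseline[gi[g]] + sign * lam * f
                             + np.sqrt(1.0 - lam ** 2)
                             * rng.normal(size=n_samples))

    counts = rng.poisson(np.minimum(2.0 ** values, 1e6)).astype(float)
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        counts=pd.DataFrame(counts, index=genes, columns=samples))

    auc = np.empty((n_drugs, n_samples))
    truth: dict[str, dict] = {}
    drug_ids = [f"drug{k:02d}" for k in range(n_drugs)]
    for k, drug in enumerate(drug_ids):
        c = k % len(planted_cliques)
        raw = factors[c] + noise_sd * rng.normal(size=n_samples)
        auc[k] = _auc_transform(raw, auc_scale)
        mask = rng.random(n_samples) < missing_frac
        auc[k, mask] = np.nan
        module = planted_cliques[c][:module_size]
        signs = {g: ("positive" if j < module_size // 2 else "negative")
                 for j, g in enumerate(module)}
        truth[drug] = {
            "genes": list(module),
            "signs": signs,
            "loading": lam,
            "noise_sd": noise_sd,
            "clique_index": c,
            "missing_mask": mask.copy(),
            "n_measured": int(n_samples - mask.sum()),
        }
    resp = DrugResponseMatrix(
        auc=pd.DataFrame(auc, index=drug_ids, columns=samples))

    sets: dict[str, tuple[str, list[str]]] = {}
    for c, members in enumerate(planted_cliques):
        module = members[:module_size]
        half = module_size // 2
        sets[f"planted_pos_{c}"] = ("planted positive-loading module",
                                    module[:half])
        sets[f"planted_neg_{c}"] = ("planted negative-loading module",
                                    module[half:])
    for j in range(8):
        decoy = sorted(str(v) for v in rng.choice(
            genes, size=min(20, len(genes)), replace=False))
        sets[f"decoy_{j}"] = ("random decoy set", decoy)

    return SyntheticCohort(expr=expr, resp=resp, net=net,
                           sets=GeneSetCollection(sets=sets), truth=truth,
                           planted_cliques=[list(c)
                                            for c in planted_cliques])


def planted_proximity_instance(net: PPINetwork,
                               planted_cliques: list[list[str]],
                               n_targets: int = 5,
                               signature_size: int = 8
                               ) -> tuple[list[str], list[str]]:
    """Hub-adjacent target and signature sets for proximity testing.

    The signature is drawn from a planted clique (well-connected nodes);
    the targets are the lowest-degree neighbors of the signature outside
    the clique, so every target sits one hop from the signature while a
    degree-matched random target of the same (low) degree typically does
    not. Returns (targets, signature genes).
    """
    g = net.graph
    clique = planted_cliques[0]
    signature = clique[:signature_size]
    candidates = sorted(
        {v for s in signature for v in g.neighbors(s)} - set(clique),
        key=lambda v: (g.degree(v), v))
    if len(candidates) < n_targets:
        raise ValueError("not enough clique-adjacent candidates")
    return candidates[:n_targets], signature


# ---------------------------------------------------------------------------
# hand-specified fixtures with embedded expected outputs

def _qc_toy() -> dict:
    samples = [f"S{i}" for i in range(1, 7)] + ["S_empty", "S_allex"]
    drugs = ["D_ok1", "D_ok2", "D_extreme", "D_fewn"]
    auc = pd.DataFrame(np.nan, index=drugs, columns=samples)
    auc.loc["D_ok1", ["S1", "S2", "S3", "S4", "S5", "S6"]] = \
        [100.0, 120.0, 140.0, 160.0, 180.0, 200.0]
    auc.loc["D_ok1", "S_allex"] = 260.0
    auc.loc["D_ok2", ["S1", "S2", "S3", "S4", "S5", "S6"]] = \
        [50.0, 60.0, 70.0, 80.0, 90.0, 240.0]
    auc.loc["D_ok2", "S_allex"] = 280.0
    auc.loc["D_extreme", ["S1", "S2", "S3", "S4", "S5", "S6"]] = \
        [260.0, 270.0, 280.0, 290.0, 300.0, 310.0]
    auc.loc["D_fewn", ["S1", "S2"]] = [110.0, 130.0]
    counts = pd.DataFrame(
        {s: 0.0 for s in samples},
        index=["g_pass", "g_fail"])
    counts.loc["g_pass", "S1"] = 2.0            # >1 in 1/8 samples >= ceil(0.8)
    counts.loc["g_fail"] = 1.0                  # never strictly > 1
    values = np.log2(counts + 1.0)
    return {
        "resp": DrugResponseMatrix(auc=auc),
        "expr": ExpressionMatrix(values=values, counts=counts),
        "threshold": 250.0,
        "min_n": 3,
        "extreme_fraction": 0.9,
        "gene_min_count": 1.0,
        "gene_min_fraction": 0.10,
        "expected": {
            "kept_samples": ["S1", "S2", "S3", "S4", "S5", "S6"],
            "dropped_samples": {"S_empty": "no_data",
                                "S_allex": "all_extreme"},
            "kept_drugs": ["D_ok1", "D_ok2"],
            "dropped_drugs": {"D_extreme": "extreme_fraction",
                              "D_fewn": "min_n"},
            "kept_genes": ["g_pass"],
            "dropped_genes": {"g_fail": "low_expression"},
        },
    }


def _path_graph() -> dict:
    g = nx.path_graph(["a", "b", "c", "d"])
    return {
        "graph": g,
        "expected": {
            ("a,d", "b"): 1.5,          # (1 + 2) / 2
            ("a", "c,d"): 2.0,          # min(2, 3)
            ("a,b", "a,b"): 0.0,        # targets inside the signature
        },
    }


def _two_node_diffusion() -> dict:
    g = nx.Graph([("x", "y")])
    f = np.array([[2.0 / 3.0, 1.0 / 3.0],
                  [1.0 / 3.0, 2.0 / 3.0]])
    return {"graph": g, "beta": 0.5, "nodes": ["x", "y"], "expected_F": f}


def _diamond_6node() -> dict:
    # a touches both seeds; b touches one seed and one non-seed
    g = nx.Graph()
    g.add_edges_from([("s1", "a"), ("s2", "a"), ("s1", "b"), ("n1", "b"),
                      ("n1", "n2"), ("s2", "n2")])
    return {"graph": g, "seeds": ["s1", "s2"], "alpha": 1,
            "expected_first": "a"}


def _auroc_vectors() -> dict:
    return {"cases": [
        {"scores": [1, 2, 3, 4], "labels": [0, 0, 1, 1], "expected": 1.0},
        {"scores": [1, 2, 3, 4], "labels": [0, 1, 0, 1], "expected": 0.75},
        {"scores": [5, 5, 5, 5], "labels": [0, 1, 0, 1], "expected": 0.5},
        {"scores": [4, 3, 2, 1], "labels": [0, 0, 1, 1], "expected": 0.0},
    ]}


_CATALOG = {
    "qc_toy": _qc_toy,
    "path_graph": _path_graph,
    "two_node_diffusion": _two_node_diffusion,
    "diamond_6node": _diamond_6node,
    "auroc_vectors": _auroc_vectors,
}


def toy_fixture(name: str) -> dict:
    """Hand-specified fixture bundle with expected outputs embedded."""
    if name not in _CATALOG:
        raise KeyError(f"unknown fixture {name!r}; "
                       f"catalog: {sorted(_CATALOG)}")
    return _CATALOG[name]()
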