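"""Shared fixtures: toy bundles and the synthetic study cohort.

The study cohort (200 samples, planted 30-gene modules at |rho| ~ 0.5 on a
300-node scale-free network) is expensive to analyse, so the full pipeline
result is computed once per session and shared by the recovery tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from netaml.config import AnalysisConfig
from netaml.pipeline import run_pipeline
from netaml.simulate import (simulate_cohort, simulate_ppi, toy_fixture)

STUDY_SEED = 42


@pytest.fixture(scope="session")
def study_cfg() -> AnalysisConfig:
    """Defaults, with the module-expansion budget scaled to the network.

    The expansion cap of 200 added genes is calibrated to a full-size
    interactome (~17k nodes); on the 300-node synthetic network the
    equivalent budget is a handful of genes.
    """
    return AnalysisConfig(random_seed=STUDY_SEED, diamond_max_nodes=5)


@pytest.fixture(scope="session")
def study_network():
    return simulate_ppi(300, planted_cliques=(30, 30), seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_cohort(study_network):
    net, cliques = study_network
    return simulate_cohort(net, cliques, n_samples=200, n_drugs=2,
                           module_size=30, effect_rho=0.5, noise_sd=0.5,
                           missing_frac=0.10, auc_scale=300.0,
                           seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_run(study_network, study_cohort, study_cfg):
    net, _ = study_network
    return run_pipeline(study_cohort.expr, study_cohort.resp, net,
                        study_cohort.sets, study_cfg, drugs=["drug00"])


@pytest.fixture()
def qc_toy():
    return toy_fixture("qc_toy")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def small_random_graphs(max_nodes: int = 12, n_graphs: int = 20,
                        seed: int = 0):
    """Connected random graphs with <= max_nodes nodes (oracle suites)."""
    import networkx as nx
    rng = np.random.default_rng(seed)
    graphs = []
    while len(graphs) < n_graphs:
        n = int(rng.integers(4, max_nodes + 1))
        p = float(rng.uniform(0.25, 0.7))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2 ** 31)))
        if not nx.is_connected(g):
            continue
        graphs.append(nx.relabel_nodes(g, {i: f"v{i:02d}" for i in g}))
    return graphs
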