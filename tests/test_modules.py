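from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pytest

from netaml.config import AnalysisConfig
from netaml.modules import (DrugModuleSet, assemble_feature_sets,
                            diamond_expand, expand_module_set, hot_modules,
                            insulated_diffusion_matrix)
from netaml.simulate import toy_fixture
from tests.conftest import small_random_graphs


class TestDiffusion:
    def test_two_node_kernel_exact(self):
        fx = toy_fixture("two_node_diffusion")
        f = insulated_diffusion_matrix(fx["graph"], fx["beta"],
                                       nodes=fx["nodes"])
        assert np.abs(f.to_numpy() - fx["expected_F"]).max() < 1e-12

    def test_beta_near_one_is_identity(self):
        g = nx.path_graph(5)
        f = insulated_diffusion_matrix(g, 1 - 1e-9).to_numpy()
        assert np.abs(f - np.eye(5)).max() < 1e-6

    def test_columns_sum_to_one_random_graphs(self):
        for g in small_random_graphs(max_nodes=25, n_graphs=15, seed=3):
            f = insulated_diffusion_matrix(g, 0.5).to_numpy()
            assert np.abs(f.sum(axis=0) - 1.0).max() < 1e-10
            assert f.min() >= 0

    def test_isolated_node_keeps_its_heat(self):
        g = nx.Graph([("a", "b")])
        g.add_node("lonely")
        f = insulated_diffusion_matrix(g, 0.5, nodes=["a", "b", "lonely"])
        np.testing.assert_allclose(f["lonely"].to_numpy(), [0, 0, 1],
                                   atol=1e-12)

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            insulated_diffusion_matrix(nx.path_graph(3), 1.0)


def brute_force_diamond(g: nx.Graph, seeds: list[str],
                        max_added: int) -> list[str]:
    """Exact-rational reference expansion at alpha=1 (factorial tails)."""
    module = set(seeds)
    added = []
    n = g.number_of_nodes()

    def tail(k_in, s, k):
        lo, hi = max(k_in, 0, k - (n - s)), min(s, k)
        if lo > hi:
            return Fraction(0)
        return Fraction(sum(comb(s, i) * comb(n - s, k - i)
                            for i in range(lo, hi + 1)), comb(n, k))

    while len(added) < max_added:
        cands = {v for m in module for v in g.neighbors(m)} - module
        if not cands:
            break
        best = None
        for v in sorted(cands):
            k = g.degree(v)
            k_in = sum(1 for u in g.neighbors(v) if u in module)
            key = (tail(k_in, len(module), k), -k, v)
            if best is None or key < best[0]:
                best = (key, v)
        added.append(best[1])
        module.add(best[1])
    return added


class TestDiamond:
    def test_six_node_fixture_first_addition(self):
        fx = toy_fixture("diamond_6node")
        added = diamond_expand(fx["graph"], fx["seeds"], max_added=1,
                               alpha=fx["alpha"])
        assert added == [fx["expected_first"]]

    def test_star_hub_seed_ties_break_lexicographically(self):
        g = nx.star_graph(5)
        g = nx.relabel_nodes(g, {0: "hub", 1: "a", 2: "b", 3: "c",
                                 4: "d", 5: "e"})
        added = diamond_expand(g, ["hub"], max_added=3, alpha=1)
        assert added == ["a", "b", "c"]

    def test_alpha1_matches_brute_force_on_small_graphs(self):
        for g in small_random_graphs(max_nodes=12, n_graphs=12, seed=5):
            seeds = sorted(g.nodes)[:2]
            got = diamond_expand(g, seeds, max_added=6, alpha=1)
            assert got == brute_force_diamond(g, seeds, 6)

    def test_empty_seed_list_rejected(self):
        with pytest.raises(ValueError):
            diamond_expand(nx.path_graph(4), [], max_added=1)

    def test_seed_weight_prioritizes_seed_links(self):
        # after A joins, m1 links to the seed while x1 links only to the
        # added gene A; a high seed weight pulls m1 ahead of x1
        g = nx.Graph([("s", "m1"), ("s", "m2"), ("m1", "m2"),
                      ("s", "A"), ("A", "x1"),
                      ("m1", "B"), ("m2", "B")])
        assert diamond_expand(g, ["s"], 3, alpha=1) == ["A", "x1", "m1"]
        assert diamond_expand(g, ["s"], 3, alpha=10) == ["A", "m1", "m2"]


class TestHotModules:
    def test_planted_clique_recovered_whole(self):
        g = nx.gnm_random_graph(100, 200, seed=42)
        g = nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes})
        clique = [f"n{i:03d}" for i in range(8)]
        for i, a in enumerate(clique):
            for b in clique[i + 1:]:
                g.add_edge(a, b)
        cfg = AnalysisConfig(n_permutations=200)
        ms = hot_modules(g, {v: 5.0 for v in clique}, cfg, seed=42)
        assert ms.modules and set(clique) <= set(ms.modules[0])

    def test_zero_heat_yields_no_modules(self):
        g = nx.gnm_random_graph(50, 100, seed=1)
        cfg = AnalysisConfig(n_permutations=50)
        ms = hot_modules(g, {n: 0.0 for n in g.nodes}, cfg, seed=1)
        assert ms.modules == []

    def test_no_seed_on_network_warns_empty(self, caplog):
        g = nx.path_graph([f"p{i}" for i in range(10)])
        cfg = AnalysisConfig(n_permutations=50)
        ms = hot_modules(g, {"absent": 3.0}, cfg, seed=0)
        assert ms.modules == []

    def test_modules_disjoint_and_size_sorted(self, study_run):
        ms = study_run.drugs["drug00"].modules
        seen = set()
        for m in ms.modules:
            assert not (set(m) & seen)
            seen |= set(m)
        sizes = [len(m) for m in ms.modules]
        assert sizes == sorted(sizes, reverse=True)

    def test_negative_heat_rejected(self):
        g = nx.path_graph(["a", "b", "c", "d", "e"])
        cfg = AnalysisConfig(n_permutations=10)
        with pytest.raises(ValueError):
            hot_modules(g, {"a": -1.0}, cfg)

    def test_relabeling_permutes_output(self):
        g = nx.gnm_random_graph(60, 120, seed=7)
        g = nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes})
        clique = [f"n{i:03d}" for i in range(7)]
        for i, a in enumerate(clique):
            for b in clique[i + 1:]:
                g.add_edge(a, b)
        heat = {v: 4.0 for v in clique}
        cfg = AnalysisConfig(n_permutations=100)
        ms1 = hot_modules(g, heat, cfg, seed=3)
        mapping = {v: f"x{v}" for v in g.nodes}
        ms2 = hot_modules(nx.relabel_nodes(g, mapping),
                          {mapping[v]: h for v, h in heat.items()},
                          cfg, seed=3)
        got = [sorted(mapping[v] for v in m) for m in ms1.modules]
        assert got == [sorted(m) for m in ms2.modules]


class TestExpansionAndFeatures:
    def test_expansion_inherits_majority_sign(self):
        # seed triangle, two positive seeds adjacent to the new node
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"),
                      ("a", "v"), ("b", "v")])
        ms = DrugModuleSet(drug_id="d", modules=[["a", "b", "c"]])
        cfg = AnalysisConfig(diamond_max_nodes=1, diamond_alpha=1)
        out = expand_module_set(g, ms, {"a": "positive", "b": "positive",
                                        "c": "negative"}, cfg)
        assert "v" in out.modules[0]
        assert out.sign_labels["v"] == "positive"
        assert out.provenance["v"] == "diamond"

    def test_feature_sets_single_module(self):
        ms = DrugModuleSet(drug_id="d", modules=[["a", "b", "c"]])
        fm = assemble_feature_sets(ms, ["a", "z"])
        assert fm["SCG"] == ["a", "z"]
        assert fm["M1"] == ["a", "b", "c"]
        assert "M2" not in fm and "M1plus2" not in fm

    def test_feature_sets_union(self):
        ms = DrugModuleSet(drug_id="d",
                           modules=[["a", "b", "c"], ["c", "d"]])
        fm = assemble_feature_sets(ms, ["a"])
        assert fm["M1plus2"] == ["a", "b", "c", "d"]
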