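import itertools

import numpy as np
import pandas as pd
import pytest

from netaml import models
from netaml.config import AnalysisConfig
from netaml.io import DrugResponseMatrix, ExpressionMatrix
from netaml.simulate import toy_fixture


class TestSplit:
    def test_seventy_thirty(self):
        train, test = models.split_cohort([f"s{i}" for i in range(100)],
                                          0.70, seed=0)
        assert len(train) == 70 and len(test) == 30
        assert not set(train) & set(test)

    def test_same_seed_same_split(self):
        ids = [f"s{i}" for i in range(50)]
        assert models.split_cohort(ids, 0.7, 5) == \
            models.split_cohort(ids, 0.7, 5)

    def test_floor_on_train_size(self):
        train, test = models.split_cohort([f"s{i}" for i in range(35)],
                                          0.70, seed=1)
        assert (len(train), len(test)) == (24, 11)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            models.split_cohort(["a", "b"], 0.7, 0)


def brute_force_auroc(scores, labels) -> float:
    """Concordant-pair counting with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAUROC:
    def test_fixture_vectors(self):
        for case in toy_fixture("auroc_vectors")["cases"]:
            assert models.evaluate_auroc(case["scores"], case["labels"]) \
                == pytest.approx(case["expected"])

    def test_matches_pair_counting_exhaustively(self, rng):
        for n in range(2, 9):
            scores = rng.integers(0, 4, size=n).astype(float)
            for labels in itertools.product([0, 1], repeat=n):
                if len(set(labels)) < 2:
                    continue
                got = models.evaluate_auroc(scores, list(labels))
                assert got == pytest.approx(
                    brute_force_auroc(scores, labels), abs=1e-12)

    def test_single_class_undefined(self):
        assert np.isnan(models.evaluate_auroc([1, 2, 3], [1, 1, 1]))


class TestFeatureSelection:
    def _planted(self, rng, n=120, n_noise=50):
        x = pd.DataFrame(rng.normal(size=(n, n_noise + 2)),
                         columns=[f"g{i}" for i in range(n_noise + 2)])
        y = 3.0 * x["g0"].to_numpy() - 2.0 * x["g1"].to_numpy()
        return x, y

    def test_lasso_recovers_noiseless_support(self, rng):
        x, y = self._planted(rng)
        kept = models.select_features(x, y, "lasso", seed=42)
        assert {"g0", "g1"} <= set(kept)

    def test_none_is_identity(self, rng):
        x, y = self._planted(rng)
        assert models.select_features(x, y, "none") == list(x.columns)

    def test_tree_importance_keeps_signal(self, rng):
        x, y = self._planted(rng)
        kept = models.select_features(x, y, "tree", seed=42)
        assert {"g0", "g1"} <= set(kept)
        assert len(kept) < x.shape[1]

    def test_never_returns_empty(self, rng):
        x = pd.DataFrame(rng.normal(size=(40, 10)),
                         columns=[f"g{i}" for i in range(10)])
        y = rng.normal(size=40)        # pure noise
        for method in ("lasso", "tree", "rfe_cv"):
            kept = models.select_features(x, y, method, seed=0)
            assert len(kept) >= 1

    def test_constant_response_rejected(self, rng):
        x = pd.DataFrame(rng.normal(size=(20, 3)),
                         columns=list("abc"))
        with pytest.raises(ValueError):
            models.select_features(x, np.ones(20), "lasso")


def _linear_cohort(seed=0, n=80, n_genes=12):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n)]
    vals = rng.normal(size=(n_genes, n))
    y = 100 + 20 * vals[0] - 15 * vals[1]
    expr = ExpressionMatrix(values=pd.DataFrame(vals, index=genes,
                                                columns=samples))
    resp = DrugResponseMatrix(auc=pd.DataFrame([y], index=["d"],
                                               columns=samples))
    return expr, resp


@pytest.fixture(scope="module")
def grid():
    expr, resp = _linear_cohort()
    cfg = AnalysisConfig(min_samples_per_drug=35, random_seed=7)
    registry = {"ols": models.default_registry(7)["ols"],
                "ridge_a1": models.default_registry(7)["ridge_a1"]}
    feature_map = {"SCG": list(expr.gene_ids),
                   "M1": list(expr.gene_ids)[:6]}
    results = models.run_scenarios(expr, resp, "d", feature_map, cfg,
                                   registry=registry, seed=7)
    return expr, resp, cfg, registry, results


class TestScenarios:
    def test_grid_cardinality(self, grid):
        *_, results = grid
        assert len(results) == 2 * len(models.SELECTORS) * 2

    def test_failed_plus_succeeded_conserved(self, grid):
        *_, results = grid
        assert sum(r.failed for r in results) + \
            sum(not r.failed for r in results) == len(results)

    def test_noiseless_signal_recovered(self, grid):
        *_, results = grid
        best = max((r for r in results if not r.failed),
                   key=lambda r: r.test_spearman)
        assert best.test_spearman >= 0.95

    def test_deterministic_rerun(self, grid):
        expr, resp, cfg, registry, results = grid
        again = models.run_scenarios(
            expr, resp, "d", {"SCG": list(expr.gene_ids),
                              "M1": list(expr.gene_ids)[:6]},
            cfg, registry=registry, seed=7)
        for a, b in zip(results, again):
            assert a.scenario == b.scenario
            assert a.test_auroc == b.test_auroc
            assert a.cv_spearman == b.cv_spearman

    def test_pick_best_and_roundtrip(self, grid, tmp_path):
        expr, resp, cfg, registry, results = grid
        best = models.pick_best(results, expr, resp, cfg,
                                registry_order=list(registry), seed=7)
        best.save(tmp_path / "m.joblib")
        again = models.TrainedSignatureModel.load(tmp_path / "m.joblib")
        pred, _ = models.predict_bulk(again, expr)
        np.testing.assert_array_equal(
            pred[again.test_samples].to_numpy(),
            again.test_predictions.to_numpy())


class TestPickBestTieChain:
    def _res(self, auroc, cv, n_genes, reg):
        r = models.ModelResult(
            scenario=models.ModelScenario("d", "SCG", "none", reg),
            selected_genes=[f"g{i}" for i in range(n_genes)],
            cv_spearman=cv, test_spearman=0.5, test_auroc=auroc)
        return r

    def _winner(self, results):
        rank = {"r1": 0, "r2": 1}

        def key(r):
            return (-r.test_auroc, -r.cv_spearman,
                    len(r.selected_genes), rank[r.scenario.regressor_id])
        return min(results, key=key)

    def test_auroc_dominates(self):
        a, b = self._res(0.9, 0.1, 9, "r1"), self._res(0.8, 0.9, 1, "r2")
        assert self._winner([a, b]) is a

    def test_cv_breaks_auroc_tie(self):
        a, b = self._res(0.9, 0.6, 9, "r1"), self._res(0.9, 0.5, 1, "r2")
        assert self._winner([a, b]) is a

    def test_parsimony_breaks_full_tie(self):
        a, b = self._res(0.9, 0.6, 9, "r1"), self._res(0.9, 0.6, 2, "r2")
        assert self._winner([a, b]) is b


@pytest.fixture(scope="module")
def trained():
    expr, resp = _linear_cohort(seed=3)
    cfg = AnalysisConfig(random_seed=3)
    registry = {"ols": models.default_registry(3)["ols"]}
    fm = {"SCG": list(expr.gene_ids)}
    results = models.run_scenarios(expr, resp, "d", fm, cfg,
                                   registry=registry, seed=3)
    best = models.pick_best(results, expr, resp, cfg,
                            registry_order=["ols"], seed=3)
    return expr, best


class TestPrediction:
    def test_training_matrix_reproduces_test_predictions(self, trained):
        expr, best = trained
        pred, flags = models.predict_bulk(best, expr)
        assert flags["n_imputed_genes"] == 0
        np.testing.assert_allclose(
            pred[best.test_samples].to_numpy(),
            best.test_predictions.to_numpy())

    def test_missing_gene_equals_mean_substitution(self, trained):
        expr, best = trained
        dropped = best.genes[0]
        reduced = expr.subset(genes=[g for g in expr.gene_ids
                                     if g != dropped])
        pred_missing, flags = models.predict_bulk(best, reduced)
        assert flags["n_imputed_genes"] == 1
        manual = expr.values.copy()
        manual.loc[dropped] = best.gene_means[dropped]
        pred_manual, _ = models.predict_bulk(
            best, ExpressionMatrix(values=manual))
        np.testing.assert_allclose(pred_missing.to_numpy(),
                                   pred_manual.to_numpy())

    def test_low_coverage_flagged(self, trained):
        expr, best = trained
        reduced = expr.subset(genes=[g for g in expr.gene_ids
                                     if g not in set(best.genes)])
        _, flags = models.predict_bulk(best, reduced)
        assert flags["n_imputed_genes"] == len(best.genes)
        assert flags["low_coverage"]

    def test_identical_cells_identical_predictions(self, trained):
        expr, best = trained
        col = expr.values.iloc[:, [0]]
        cells = pd.concat([col, col, col], axis=1)
        cells.columns = ["c1", "c2", "c3"]
        raw, scaled = models.predict_cells(
            [best], ExpressionMatrix(values=cells))
        assert raw.loc[:, "c1"].equals(raw.loc[:, "c2"])
        assert (scaled.to_numpy() == 0).all()    # constant -> zeros

    def test_minmax_layer_spans_unit_interval(self, trained):
        expr, best = trained
        raw, scaled = models.predict_cells([best], expr)
        assert scaled.min(axis=1).iloc[0] == 0.0
        assert scaled.max(axis=1).iloc[0] == 1.0
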