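"""Per-drug supervised model selection and prediction.

For each drug the pipeline fits every combination of

* a feature set (all SCGs, module 1, module 2, or their union),
* a feature selector (none, recursive elimination with CV, L1 support,
  tree-importance), and
* a regressor drawn from a configurable registry of mostly linear-family
  learners,

on a 70/30 train/test split of the cohort. Each scenario records the
cross-validated Spearman correlation on the training side and, on the
held-out test side, the Spearman correlation between predicted and observed
AUC and the AUROC of the predicted AUC against observed AUC binarized at
the training-set median ("resistant" = above the median, since a larger
area under the dose-response curve means less cell killing). The winner is
the scenario with the highest test AUROC, with ties resolved by training CV
correlation, then by parsimony (fewer selected genes), then registry order.

The winning model is persisted together with the per-gene training means so
that prediction on a new cohort (bulk samples or single cells) can impute
genes absent from the new matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.feature_selection import RFECV
from sklearn.linear_model import (BayesianRidge, ElasticNet, HuberRegressor,
                                  Lasso, LassoCV, LinearRegression, Ridge,
                                  TheilSenRegressor)
from sklearn.metrics import make_scorer
from sklearn.model_selection import KFold, cross_val_predict
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVR

from .config import AnalysisConfig
from .io import DrugResponseMatrix, ExpressionMatrix

logger = logging.getLogger("netaml")

__all__ = [
    "ModelScenario", "ModelResult", "TrainedSignatureModel",
    "default_registry", "split_cohort", "select_features", "run_scenarios",
    "evaluate_auroc", "pick_best", "predict_bulk", "predict_cells",
]

FEATURE_SETS = ("SCG", "M1", "M2", "M1plus2")
SELECTORS = ("none", "rfe_cv", "lasso", "tree")


def default_registry(seed: int = 0) -> dict[str, object]:
    """Shipped regressor registry: linear family plus a few baselines.

    Every entry is a scikit-learn estimator (scaling included where the
    learner is scale-sensitive); callers may pass their own mapping to
    :func:`run_scenarios` to grow or shrink the grid.
    """
    def scaled(est):
        return Pipeline([("scale", StandardScaler()), ("reg", est)])

    return {
        "ols": scaled(LinearRegression()),
        "ridge_a1": scaled(Ridge(alpha=1.0)),
        "ridge_a10": scaled(Ridge(alpha=10.0)),
        "lasso_a01": scaled(Lasso(alpha=0.1, max_iter=5000)),
        "lasso_a1": scaled(Lasso(alpha=1.0, max_iter=5000)),
        "elastic_net": scaled(ElasticNet(alpha=0.1, l1_ratio=0.5,
                                         max_iter=5000)),
        "huber": scaled(HuberRegressor(max_iter=500)),
        "theil_sen": scaled(TheilSenRegressor(random_state=seed,
                                              max_subpopulation=2000)),
        "bayesian_ridge": scaled(BayesianRidge()),
        "pls_2comp": scaled(PLSRegression(n_components=2)),
        "linear_svr": scaled(LinearSVR(random_state=seed, max_iter=5000,
                                       dual="auto")),
        "knn_5": scaled(KNeighborsRegressor(n_neighbors=5)),
        "random_forest": RandomForestRegressor(n_estimators=100,
                                               random_state=seed),
        "gbm": GradientBoostingRegressor(n_estimators=100,
                                         random_state=seed),
    }


@dataclass
class ModelScenario:
    drug_id: str
    feature_set: str
    selector: str
    regressor_id: str
    hyperparams: dict = field(default_factory=dict)


@dataclass
class ModelResult:
    scenario: ModelScenario
    selected_genes: list[str] = field(default_factory=list)
    cv_spearman: float = float("nan")
    test_spearman: float = float("nan")
    test_auroc: float = float("nan")
    n_train: int = 0
    n_test: int = 0
    failed: bool = False
    error: str = ""


@dataclass
class TrainedSignatureModel:
    """Persisted winner: fitted predictor plus what prediction needs."""

    result: ModelResult
    predictor: object
    gene_means: pd.Series            # training means, imputation fill
    auroc_threshold: float           # training-median AUC used for labels
    train_samples: list[str] = field(default_factory=list)
    test_samples: list[str] = field(default_factory=list)
    test_predictions: pd.Series | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.gene_means.index)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, Path(path))

    @staticmethod
    def load(path: str | Path) -> "TrainedSignatureModel":
        return joblib.load(Path(path))


def split_cohort(sample_ids: list[str], train_fraction: float = 0.70,
                 seed: int = 0, min_samples: int = 6
                 ) -> tuple[list[str], list[str]]:
    """Deterministic disjoint train/test split (floor on the train size)."""
    ids = list(sample_ids)
    if len(ids) < min_samples:
        raise ValueError(f"need >= {min_samples} samples to split; "
                         f"got {len(ids)}")
    order = np.random.default_rng(seed).permutation(len(ids))
    n_train = int(np.floor(train_fraction * len(ids)))
    train = [ids[i] for i in sorted(order[:n_train])]
    test = [ids[i] for i in sorted(order[n_train:])]
    return train, test


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.spearmanr(a, b).statistic)


def _top_univariate(x: pd.DataFrame, y: np.ndarray) -> str:
    rhos = {g: abs(_spearman(x[g].to_numpy(), y)) for g in x.columns}
    return max(rhos, key=lambda g: (np.nan_to_num(rhos[g], nan=-1.0), g))


def select_features(x: pd.DataFrame, y: np.ndarray, method: str = "none",
                    seed: int = 0, cv_folds: int = 5) -> list[str]:
    """Reduce a candidate feature set to the genes worth fitting.

    ``none`` keeps everything; ``rfe_cv`` is recursive feature elimination
    with cross-validation (ridge base learner, Spearman scoring);
    ``lasso`` keeps the non-zero support of an L1 path with CV-chosen
    penalty; ``tree`` keeps features whose random-forest importance exceeds
    the mean importance. Never returns an empty list: an all-noise input
    falls back to the single best univariate feature (logged).
    """
    if np.std(y) == 0:
        raise ValueError("constant response: feature selection undefined")
    genes = list(x.columns)
    if method == "none":
        return genes
    if len(genes) == 1:
        return genes
    xs = StandardScaler().fit_transform(x.to_numpy(dtype=float))
    cv = KFold(n_splits=min(cv_folds, len(y) // 2), shuffle=False)
    if method == "rfe_cv":
        scorer = make_scorer(lambda yt, yp: np.nan_to_num(
            _spearman(yt, yp), nan=-1.0))
        step = max(1, len(genes) // 10)
        sel = RFECV(Ridge(alpha=1.0), step=step, cv=cv, scoring=scorer,
                    min_features_to_select=1)
        sel.fit(xs, y)
        keep = [g for g, s in zip(genes, sel.support_) if s]
    elif method == "lasso":
        model = LassoCV(cv=cv, random_state=seed, max_iter=10000)
        model.fit(xs, y)
        keep = [g for g, c in zip(genes, model.coef_) if c != 0.0]
    elif method == "tree":
        forest = RandomForestRegressor(n_estimators=200, random_state=seed)
        forest.fit(x.to_numpy(dtype=float), y)
        imp = forest.feature_importances_
        keep = [g for g, i in zip(genes, imp) if i > imp.mean()]
    else:
        raise ValueError(f"unknown selector {method!r}")
    if not keep:
        fallback = _top_univariate(x, y)
        logger.warning("selector %s kept nothing; falling back to %r",
                       method, fallback)
        keep = [fallback]
    return keep


def evaluate_auroc(scores, labels) -> float:
    """Rank-based AUROC (Mann-Whitney form); ties contribute one half.

    ``labels`` are binary with 1 = positive class; ``scores`` rank the
    positives above the negatives when AUROC is 1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        logger.warning("AUROC undefined: single-class labels")
        return float("nan")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def run_scenarios(expr: ExpressionMatrix, resp: DrugResponseMatrix,
                  drug: str, feature_map: dict[str, list[str]],
                  cfg: AnalysisConfig,
                  registry: dict[str, object] | None = None,
                  seed: int | None = None) -> list[ModelResult]:
    """Fit the full feature-set x selector x regressor grid for one drug.

    A failed fit is recorded (``failed=True``) rather than raised, so the
    count of failed plus succeeded scenarios always equals the grid size.
    Feature selection runs once per (feature set, selector) pair and is
    shared across regressors.
    """
    if seed is None:
        seed = cfg.random_seed
    if registry is None:
        registry = default_registry(seed)
    y_all = resp.auc.loc[drug].dropna()
    samples = [s for s in y_all.index if s in expr.values.columns]
    if len(samples) < cfg.min_samples_per_drug:
        raise ValueError(f"drug {drug}: {len(samples)} paired samples "
                         f"< min_samples_per_drug={cfg.min_samples_per_drug}")
    train, test = split_cohort(samples, cfg.train_fraction, seed)
    x_full = expr.values.T     # samples x genes
    y_train = y_all[train].to_numpy(dtype=float)
    y_test = y_all[test].to_numpy(dtype=float)
    threshold = float(np.median(y_train))
    labels_test = (y_test > threshold).astype(int)   # 1 = resistant

    results: list[ModelResult] = []
    for fset, genes in feature_map.items():
        genes = [g for g in genes if g in x_full.columns]
        if not genes:
            continue
        x_train = x_full.loc[train, genes]
        x_test = x_full.loc[test, genes]
        for selector in SELECTORS:
            try:
                selected = select_features(x_train, y_train, selector,
                                           seed=seed, cv_folds=cfg.cv_folds)
            except Exception as exc:      # selection failure fails the row
                for reg_id in registry:
                    results.append(ModelResult(
                        ModelScenario(drug, fset, selector, reg_id),
                        failed=True, error=f"selector: {exc}"))
                continue
            xt = x_train[selected].to_numpy(dtype=float)
            xv = x_test[selected].to_numpy(dtype=float)
            cv = KFold(n_splits=min(cfg.cv_folds, len(train) // 2),
                       shuffle=False)
            for reg_id, template in registry.items():
                scen = ModelScenario(drug, fset, selector, reg_id)
                try:
                    est = clone(template)
                    cv_pred = cross_val_predict(clone(template), xt,
                                                y_train, cv=cv)
                    est.fit(xt, y_train)
                    pred = np.asarray(est.predict(xv)).ravel()
                    results.append(ModelResult(
                        scenario=scen, selected_genes=list(selected),
                        cv_spearman=_spearman(np.asarray(cv_pred).ravel(),
                                              y_train),
                        test_spearman=_spearman(pred, y_test),
                        test_auroc=evaluate_auroc(pred, labels_test),
                        n_train=len(train), n_test=len(test)))
                    results[-1].fitted = est       # kept for pick_best
                except Exception as exc:
                    results.append(ModelResult(scen, failed=True,
                                               error=str(exc)))
    return results


def pick_best(results: list[ModelResult], expr: ExpressionMatrix,
              resp: DrugResponseMatrix, cfg: AnalysisConfig,
              registry_order: list[str] | None = None,
              seed: int | None = None) -> TrainedSignatureModel:
    """Select the winning scenario and persist everything prediction needs.

    Winner: highest test AUROC, ties by higher CV Spearman, then fewer
    selected genes, then registry order.
    """
    ok = [r for r in results if not r.failed
          and np.isfinite(r.test_auroc)]
    if not ok:
        raise ValueError("no successful scenario to pick from")
    if registry_order is None:
        registry_order = list(dict.fromkeys(
            r.scenario.regressor_id for r in results))
    rank = {rid: i for i, rid in enumerate(registry_order)}

    def key(r: ModelResult):
        return (-r.test_auroc,
                -(r.cv_spearman if np.isfinite(r.cv_spearman) else -np.inf),
                len(r.selected_genes),
                rank.get(r.scenario.regressor_id, len(rank)))

    best = min(ok, key=key)
    drug = best.scenario.drug_id
    if seed is None:
        seed = cfg.random_seed
    y_all = resp.auc.loc[drug].dropna()
    samples = [s for s in y_all.index if s in expr.values.columns]
    train, test = split_cohort(samples, cfg.train_fraction, seed)
    x_train = expr.values.T.loc[train, best.selected_genes]
    x_test = expr.values.T.loc[test, best.selected_genes]
    pred = np.asarray(best.fitted.predict(
        x_test.to_numpy(dtype=float))).ravel()
    return TrainedSignatureModel(
        result=best, predictor=best.fitted,
        gene_means=x_train.mean(axis=0),
        auroc_threshold=float(np.median(y_all[train].to_numpy())),
        train_samples=train, test_samples=test,
        test_predictions=pd.Series(pred, index=test, name=drug))


def predict_bulk(model: TrainedSignatureModel, expr_new: ExpressionMatrix
                 ) -> tuple[pd.Series, dict]:
    """Predict per-sample AUC for a new cohort.

    Genes missing from the new matrix are imputed with their training
    means; the prediction carries a ``low_coverage`` flag when more than
    half of the model genes had to be imputed.
    """
    genes = model.genes
    present = [g for g in genes if g in expr_new.values.index]
    n_missing = len(genes) - len(present)
    x = pd.DataFrame(
        np.tile(model.gene_means.to_numpy(dtype=float),
                (len(expr_new.sample_ids), 1)),
        index=expr_new.sample_ids, columns=genes)
    if present:
        x.loc[:, present] = expr_new.values.loc[present].T.to_numpy()
    pred = np.asarray(model.predictor.predict(
        x.to_numpy(dtype=float))).ravel()
    flags = {"n_imputed_genes": n_missing,
             "low_coverage": n_missing > len(genes) / 2}
    if n_missing:
        logger.info("drug %s: imputed %d/%d model genes%s",
                    model.result.scenario.drug_id, n_missing, len(genes),
                    " [low coverage]" if flags["low_coverage"] else "")
    return pd.Series(pred, index=expr_new.sample_ids,
                     name=model.result.scenario.drug_id), flags


def predict_cells(models: list[TrainedSignatureModel],
                  cell_expr: ExpressionMatrix
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every cell with every drug model.

    Returns (raw drug x cell predicted AUC, per-drug min-max transformed
    layer on [0, 1]; lower = more sensitive). A drug with constant
    predictions across cells maps to all zeros (flagged in the log).
    """
    rows, scaled = [], []
    for model in models:
        pred, _ = predict_bulk(model, cell_expr)
        rows.append(pred)
        span = pred.max() - pred.min()
        if span == 0:
            logger.warning("drug %s: constant predictions across cells",
                           pred.name)
            scaled.append(pred * 0.0)
        else:
            scaled.append((pred - pred.min()) / span)
    raw = pd.DataFrame(rows)
    return raw, pd.DataFrame(scaled)
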