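import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netaml import correlation
from netaml.io import DrugResponseMatrix, ExpressionMatrix


def _cohort(x: np.ndarray, y: np.ndarray):
    """One gene per row of x, one drug with response y."""
    samples = [f"s{i}" for i in range(x.shape[1])]
    expr = ExpressionMatrix(values=pd.DataFrame(
        x, index=[f"g{i}" for i in range(x.shape[0])], columns=samples))
    resp = DrugResponseMatrix(auc=pd.DataFrame(
        [y], index=["d"], columns=samples))
    return expr, resp


class TestFisherZ:
    @pytest.mark.parametrize("rho, n, expected", [
        (0.0, 10, 0.0),
        (0.5, 39, math.atanh(0.5) * 6),     # ~3.2958
        (0.6, 39, math.atanh(0.6) * 6),     # ~4.1589
    ])
    def test_known_values(self, rho, n, expected):
        assert correlation.fisher_z(rho, n) == pytest.approx(
            expected, abs=1e-12)

    def test_exact_one_gives_signed_infinity(self):
        assert correlation.fisher_z(1.0, 10) == math.inf
        assert correlation.fisher_z(-1.0, 10) == -math.inf

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            correlation.fisher_z(0.5, 3)

    @settings(derandomize=True, max_examples=200)
    @given(rho=st.floats(-0.999, 0.999), n=st.integers(4, 500))
    def test_odd_in_rho(self, rho, n):
        assert correlation.fisher_z(-rho, n) == pytest.approx(
            -correlation.fisher_z(rho, n), abs=1e-12)

    def test_strictly_increasing_in_rho_and_n(self):
        rhos = np.linspace(-0.95, 0.95, 41)
        zs = [correlation.fisher_z(r, 30) for r in rhos]
        assert np.all(np.diff(zs) > 0)
        zs_n = [correlation.fisher_z(0.4, n) for n in range(4, 100)]
        assert np.all(np.diff(zs_n) > 0)


class TestSpearmanScreen:
    def test_perfect_antimonotone(self):
        expr, resp = _cohort(np.array([[1.0, 2.0, 3.0]]),
                             np.array([3.0, 2.0, 1.0]))
        tab = correlation.spearman_drug_gene(expr, resp)
        assert tab["rho"].iloc[0] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle_all_4perms(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        for perm in itertools.permutations([1.0, 2.0, 3.0, 4.0]):
            y = np.array(perm)
            expr, resp = _cohort(x[np.newaxis, :], y)
            got = correlation.spearman_drug_gene(expr, resp)["rho"].iloc[0]
            rx = pd.Series(x).rank().to_numpy()
            ry = pd.Series(y).rank().to_numpy()
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert got == pytest.approx(oracle, abs=1e-12)

    def test_constant_gene_flagged_not_classified(self):
        expr, resp = _cohort(np.array([[5.0, 5.0, 5.0, 5.0]]),
                             np.array([1.0, 2.0, 3.0, 4.0]))
        tab = correlation.spearman_drug_gene(expr, resp)
        tab = correlation.classify_scgs(tab)
        assert np.isnan(tab["rho"].iloc[0])
        assert tab["scg_class"].iloc[0] == "none"

    def test_pairwise_complete_n(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
        y = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        expr, resp = _cohort(x, y)
        tab = correlation.spearman_drug_gene(expr, resp)
        assert tab["n"].iloc[0] == 4

    def test_q_values_bh_per_drug(self):
        rng = np.random.default_rng(0)
        expr, resp = _cohort(rng.normal(size=(20, 30)),
                             rng.uniform(10, 300, size=30))
        tab = correlation.spearman_drug_gene(expr, resp)
        from scipy.stats import false_discovery_control
        expected = false_discovery_control(tab["p"].to_numpy(), method="bh")
        np.testing.assert_allclose(tab["q"].to_numpy(), expected)


class TestClassify:
    def _table(self, zs):
        return pd.DataFrame({
            "drug": "d", "gene": [f"g{i}" for i in range(len(zs))],
            "rho": np.tanh(np.asarray(zs)), "n": 39, "z": zs,
            "p": 0.01, "q": 0.05, "scg_class": "none"})

    def test_fixed_cutoffs(self):
        tab = correlation.classify_scgs(
            self._table([4.1589, 3.2958, -4.5, -3.9]))
        assert list(tab["scg_class"]) == ["PCG", "none", "NCG", "none"]

    def test_quantile_mode_counts(self):
        zs = list(np.linspace(0.1, 2.0, 100)) + \
             list(np.linspace(-2.0, -0.1, 60))
        tab = correlation.classify_scgs(self._table(zs), mode="quantile",
                                        top_quantile=0.05)
        n_pcg = (tab["scg_class"] == "PCG").sum()
        n_ncg = (tab["scg_class"] == "NCG").sum()
        assert n_pcg == math.ceil(0.05 * 100)
        assert n_ncg == math.ceil(0.05 * 60)

    def test_summary_additive(self):
        tab = correlation.classify_scgs(
            self._table([4.0, 4.2, 5.0, -4.5, -4.2, 1.0]))
        s = correlation.scg_summary(tab)
        assert s.loc[0, "n_pcg"] == 3
        assert s.loc[0, "n_ncg"] == 2
        assert s.loc[0, "n_scg"] == 5

    def test_empty_summary(self):
        s = correlation.scg_summary(pd.DataFrame(
            columns=correlation.COLUMNS))
        assert s.empty


class TestPlantedPower:
    def test_planted_correlated_genes_called_scgs(self, study_cohort,
                                                  study_run):
        """30 planted genes at |rho|~0.5, n~180: power is essentially 1."""
        corr = study_run.correlations
        truth = study_cohort.truth["drug00"]
        called = set(corr[(corr["drug"] == "drug00")
                          & (corr["scg_class"] != "none")]["gene"])
        recall = len(called & set(truth["genes"])) / len(truth["genes"])
        assert recall >= 0.8
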