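"""Drug-gene association screen.

For every (drug, gene) pair the screen computes a Spearman rank correlation
between the gene's normalized expression and the drug's AUC over the
pairwise-complete samples, converts it to a variance-stabilized score with
Fisher's z-transformation,

    z = atanh(rho) * sqrt(n - 3),

and calls sensitivity-correlated genes (SCGs): positively correlated genes
(PCGs, high expression tracking high AUC, i.e. resistance) above a positive
z cutoff and negatively correlated genes (NCGs) below a negative cutoff.
Benjamini-Hochberg q-values are attached per drug across its genes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import DrugResponseMatrix, ExpressionMatrix

logger = logging.getLogger("netaml")

__all__ = ["spearman_drug_gene", "fisher_z", "classify_scgs", "scg_summary"]

COLUMNS = ["drug", "gene", "rho", "n", "z", "p", "q", "scg_class"]


def fisher_z(rho: float, n: int) -> float:
    """Fisher z-transformed correlation: ``atanh(rho) * sqrt(n - 3)``.

    Under the null this is approximately standard normal, which makes
    correlations at different sample sizes comparable on one scale.
    A correlation of exactly +/-1 returns a signed infinity sentinel.
    """
    if n < 4:
        raise ValueError(f"fisher_z requires n >= 4; got n={n}")
    if abs(rho) > 1:
        raise ValueError(f"|rho| must be <= 1; got {rho}")
    if abs(rho) == 1:
        return float(np.copysign(np.inf, rho))
    return float(np.arctanh(rho) * np.sqrt(n - 3))


def _spearman_one_drug(expr_vals: pd.DataFrame, auc: pd.Series
                       ) -> pd.DataFrame:
    """Vectorized Spearman of every gene against one drug's AUC.

    Pairwise-complete on the drug side (genes are assumed fully observed
    in the normalized layer, which :class:`ExpressionMatrix` enforces).
    """
    paired = auc.dropna()
    samples = [s for s in paired.index if s in expr_vals.columns]
    n = len(samples)
    genes = expr_vals.index
    if n < 3:
        logger.warning("drug %s: only %d paired samples; correlations "
                       "undefined", auc.name, n)
        return pd.DataFrame({"gene": genes, "rho": np.nan, "n": n,
                             "p": np.nan})
    x = expr_vals[samples].to_numpy(dtype=float)
    y = paired[samples].to_numpy(dtype=float)
    rx = stats.rankdata(x, axis=1)
    ry = stats.rankdata(y)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum(axis=1) * (ry ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx @ ry) / denom
    rho[denom == 0] = np.nan          # constant gene (or constant AUC)
    rho = np.clip(rho, -1.0, 1.0)
    # two-sided p from the t approximation (the standard large-sample form)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isposinf(t)] = 0.0
    p[np.isneginf(t)] = 0.0
    return pd.DataFrame({"gene": genes, "rho": rho, "n": n, "p": p})


def spearman_drug_gene(expr: ExpressionMatrix,
                       resp: DrugResponseMatrix) -> pd.DataFrame:
    """Long-format correlation table, one row per (drug, gene).

    Columns: drug, gene, rho, n, z, p, q, scg_class (initialized "none").
    q-values are Benjamini-Hochberg within each drug; rows with undefined
    rho (constant gene, too few samples) carry NaN and never become SCGs.
    """
    frames = []
    for drug in resp.drug_ids:
        tab = _spearman_one_drug(expr.values, resp.auc.loc[drug])
        tab.insert(0, "drug", drug)
        ok = tab["rho"].notna() & (tab["n"] >= 4) & (tab["rho"].abs() < 1)
        z = np.full(len(tab), np.nan)
        z[ok] = (np.arctanh(tab.loc[ok, "rho"].to_numpy())
                 * np.sqrt(tab.loc[ok, "n"].to_numpy() - 3))
        exact = tab["rho"].abs() == 1
        z[exact & tab["rho"].notna()] = np.copysign(
            np.inf, tab.loc[exact & tab["rho"].notna(), "rho"])
        tab["z"] = z
        q = np.full(len(tab), np.nan)
        pv = tab["p"].to_numpy()
        mask = ~np.isnan(pv)
        if mask.any():
            q[mask] = stats.false_discovery_control(pv[mask], method="bh")
        tab["q"] = q
        frames.append(tab)
    out = pd.concat(frames, ignore_index=True)
    out["scg_class"] = "none"
    return out[COLUMNS]


def classify_scgs(table: pd.DataFrame, mode: str = "fixed",
                  z_pos_cutoff: float = 3.7, z_neg_cutoff: float = -4.0,
                  top_quantile: float = 0.05) -> pd.DataFrame:
    """Fill the ``scg_class`` column.

    ``fixed`` mode applies the z cutoffs directly (PCG: z > pos cutoff;
    NCG: z < neg cutoff). ``quantile`` mode instead calls the top
    ``top_quantile`` of positive-z pairs PCGs and the bottom
    ``top_quantile`` of negative-z pairs NCGs, pooled over the whole table.
    Rows with undefined z stay "none".
    """
    out = table.copy()
    z = out["z"].to_numpy()
    cls = np.array(["none"] * len(out), dtype=object)
    finite = ~np.isnan(z)
    if mode == "fixed":
        cls[finite & (z > z_pos_cutoff)] = "PCG"
        cls[finite & (z < z_neg_cutoff)] = "NCG"
    elif mode == "quantile":
        pos = finite & (z > 0)
        neg = finite & (z < 0)
        if pos.any():
            cut = np.quantile(z[pos], 1.0 - top_quantile)
            cls[pos & (z >= cut)] = "PCG"
        if neg.any():
            cut = np.quantile(z[neg], top_quantile)
            cls[neg & (z <= cut)] = "NCG"
    else:
        raise ValueError(f"mode must be 'fixed' or 'quantile'; got {mode!r}")
    # infinities carry their sign regardless of mode
    cls[np.isposinf(z)] = "PCG"
    cls[np.isneginf(z)] = "NCG"
    out["scg_class"] = cls
    return out


def scg_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-drug PCG/NCG/SCG counts (SCG = PCG + NCG)."""
    if table.empty:
        return pd.DataFrame(columns=["drug", "n_pcg", "n_ncg", "n_scg"])
    counts = (table.groupby("drug")["scg_class"]
              .value_counts().unstack(fill_value=0))
    out = pd.DataFrame({
        "drug": counts.index,
        "n_pcg": counts.get("PCG", pd.Series(0, index=counts.index)),
        "n_ncg": counts.get("NCG", pd.Series(0, index=counts.index)),
    }).reset_index(drop=True)
    out["n_scg"] = out["n_pcg"] + out["n_ncg"]
    return out
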