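"""Domain containers and file readers/writers shared by all stages.

Matrices travel as pandas DataFrames inside light wrapper classes; the
protein-interaction network is a :class:`networkx.Graph` wrapped with its
confidence bookkeeping; pathway collections are parsed from standard GMT.
All tabular formats are plain TSV so that every artifact round-trips through
text exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("netaml")

__all__ = [
    "ExpressionMatrix", "DrugResponseMatrix", "PPINetwork",
    "GeneSetCollection",
    "load_expression", "load_drug_response", "load_ppi", "load_gmt",
    "write_matrix", "log_cpm",
]


def _check_unique(ids: Iterable[str], kind: str) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dupes = sorted(s[s.duplicated()].unique())
        raise ValueError(f"duplicate {kind} identifiers: {dupes}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with an optional raw-count layer.

    ``values`` is the normalized layer used downstream (correlation,
    modeling, scoring); ``counts`` backs the expression-level gene filter.
    """

    values: pd.DataFrame
    counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        if self.counts is not None:
            if self.counts.shape != self.values.shape:
                raise ValueError("counts and values layers differ in shape")
            if not self.counts.index.equals(self.values.index) or \
                    not self.counts.columns.equals(self.values.columns):
                raise ValueError("counts and values layers differ in labels")
            if (self.counts.to_numpy(dtype=float) < 0).any():
                raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, genes: Iterable[str] | None = None,
               samples: Iterable[str] | None = None) -> "ExpressionMatrix":
        v = self.values
        c = self.counts
        if genes is not None:
            genes = [g for g in genes if g in v.index]
            v = v.loc[genes]
            c = c.loc[genes] if c is not None else None
        if samples is not None:
            samples = [s for s in samples if s in v.columns]
            v = v[samples]
            c = c[samples] if c is not None else None
        return ExpressionMatrix(values=v, counts=c)


@dataclass
class DrugResponseMatrix:
    """Drugs x samples dose-response AUC; NaN marks a missing measurement."""

    auc: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.auc.index, "drug")
        _check_unique(self.auc.columns, "sample")
        arr = self.auc.to_numpy(dtype=float)
        bad = np.argwhere(arr < 0)
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"negative AUC at drug={self.auc.index[i]!r}, "
                f"sample={self.auc.columns[j]!r}")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.auc.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.auc.columns)

    def subset(self, drugs: Iterable[str] | None = None,
               samples: Iterable[str] | None = None) -> "DrugResponseMatrix":
        a = self.auc
        if drugs is not None:
            a = a.loc[[d for d in drugs if d in a.index]]
        if samples is not None:
            a = a[[s for s in samples if s in a.columns]]
        return DrugResponseMatrix(auc=a)


@dataclass
class PPINetwork:
    """Undirected protein-interaction network with per-edge confidence.

    Edge attributes: ``confidence`` (0-1000 scale) and ``weight`` =
    confidence / 1000 in (0, 1].
    """

    graph: nx.Graph
    confidence_cutoff: float = 0.0

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops present: {loops[:3]}")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def subgraph_nodes(self, genes: Iterable[str]) -> list[str]:
        have = set(self.graph.nodes)
        return [g for g in genes if g in have]


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways); members unique within a set."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def items(self):
        for name, (_desc, genes) in self.sets.items():
            yield name, genes


# ---------------------------------------------------------------------------
# readers / writers

def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype={0: str})
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    # locate any non-numeric cell precisely before failing
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at "
            f"row={df.index[i]!r}, column={df.columns[j]!r}")
    return numeric


def load_expression(path: str | Path, *, genes_as_rows: bool = True,
                    counts: bool = False) -> ExpressionMatrix:
    """Read an expression TSV/CSV into an :class:`ExpressionMatrix`.

    Parameters
    ----------
    genes_as_rows
        When False the file is transposed (samples as rows).
    counts
        Treat the layer as raw counts; the normalized layer is then left
        unset until :func:`log_cpm` (or the caller) supplies it.
    """
    df = _read_table(path)
    if not genes_as_rows:
        df = df.T
    logger.info("loaded expression %s: %d genes x %d samples",
                path, *df.shape)
    if counts:
        return ExpressionMatrix(values=log_cpm(df), counts=df)
    return ExpressionMatrix(values=df)


def log_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(counts-per-million + 1) per sample (column)."""
    libsize = counts.sum(axis=0)
    libsize = libsize.replace(0, np.nan)
    cpm = counts.div(libsize, axis=1) * 1e6
    return np.log2(cpm.fillna(0.0) + 1.0)


def load_drug_response(path: str | Path) -> DrugResponseMatrix:
    """Read a drugs x samples AUC TSV; blank cells stay missing (NaN)."""
    df = _read_table(path)
    logger.info("loaded drug response %s: %d drugs x %d samples",
                path, *df.shape)
    return DrugResponseMatrix(auc=df)


def load_ppi(path: str | Path,
             confidence_cutoff: float = 700.0) -> PPINetwork:
    """Read a STRING-style edge list (node, node, combined score).

    Keeps edges with score strictly above ``confidence_cutoff``, drops
    self-loops, and collapses duplicate pairs keeping the maximum score.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected >= 3 columns "
                         f"(node, node, score); got {df.shape[1]}")
    # tolerate a header row of column names
    try:
        float(df.iloc[0, 2])
    except ValueError:
        df = df.iloc[1:]
    g = nx.Graph()
    for a, b, score in df.iloc[:, :3].itertuples(index=False):
        score = float(score)
        if a == b:
            continue
        if score <= confidence_cutoff:
            continue
        if g.has_edge(a, b):
            score = max(score, g[a][b]["confidence"])
        g.add_edge(a, b, confidence=score, weight=score / 1000.0)
    logger.info("loaded PPI %s: %d nodes, %d edges above %g",
                path, g.number_of_nodes(), g.number_of_edges(),
                confidence_cutoff)
    return PPINetwork(graph=g, confidence_cutoff=confidence_cutoff)


def load_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name, description, member genes)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: malformed GMT line "
                             f"(need name, description, >=1 member)")
        name, desc = parts[0], parts[1]
        members = [g for g in parts[2:] if g]
        if not members:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
        unique = list(dict.fromkeys(members))
        if len(unique) < len(members):
            logger.warning("gene set %s: %d duplicate members removed",
                           name, len(members) - len(unique))
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = (desc, unique)
    return GeneSetCollection(sets=sets)


def write_matrix(df: pd.DataFrame, path: str | Path,
                 index_label: str = "id") -> None:
    """Write a matrix as TSV, preserving full float precision."""
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.17g")


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = ["\t".join([name, desc] + genes)
             for name, (desc, genes) in collection.sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")
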