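"""Pipeline configuration.

All numeric defaults of the pipeline live in a single :class:`AnalysisConfig`
object so that every stage (QC, correlation screen, module detection, model
selection, proximity) draws its constants from one place and a YAML file can
override any of them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "load_config"]


@dataclass
class AnalysisConfig:
    """Numeric defaults for every pipeline stage.

    Parameters
    ----------
    extreme_quantile
        Pooled-AUC quantile defining the "extreme response" threshold
        (0.95 = top 5% of all measured AUCs).
    drug_extreme_fraction
        Drop a drug when strictly more than this fraction of its non-missing
        AUCs strictly exceed the extreme threshold.
    min_samples_per_drug
        Drop a drug measured in fewer than this many samples.
    gene_min_count, gene_min_fraction
        Keep a gene when its raw count strictly exceeds ``gene_min_count`` in
        at least ``ceil(gene_min_fraction * n_samples)`` samples.
    z_pos_cutoff, z_neg_cutoff
        Fisher-Z cutoffs calling positively (PCG) / negatively (NCG)
        correlated genes in fixed mode.
    scg_top_quantile
        Fraction of pairs called per sign in quantile mode.
    gsea_p_cutoff
        Permutation-p cutoff for a pathway to count as enriched.
    diffusion_beta
        Insulation (restart) parameter of the heat-diffusion kernel
        F = beta * (I - (1-beta) W)^-1; larger values keep heat local.
    n_permutations
        Heat-permutation draws for module significance.
    baseline_heat
        Heat assigned to non-seed nodes (0: unscored genes cannot enter a
        module through their own heat).
    min_module_size
        Smallest reportable module.
    max_module_iterations
        Cap on the remove-largest-module-and-rerun loop.
    consensus_cutoff
        A module is reported only if recovered in at least this many
        independent runs of the iterative procedure.
    diamond_max_nodes, diamond_alpha
        Connectivity-significance expansion: nodes added at most, and the
        weight multiplying links to the original seeds.
    string_confidence_cutoff
        Keep protein-interaction edges with confidence strictly above this
        (STRING 0-1000 scale).
    train_fraction, cv_folds
        Supervised split and inner cross-validation folds.
    proximity_null_draws
        Random gene-set draws for the proximity null distribution.
    random_seed
        Master seed; stage seeds are derived from it deterministically.
    """

    extreme_quantile: float = 0.95
    drug_extreme_fraction: float = 0.90
    min_samples_per_drug: int = 35
    gene_min_count: float = 1.0
    gene_min_fraction: float = 0.10
    z_pos_cutoff: float = 3.7
    z_neg_cutoff: float = -4.0
    scg_top_quantile: float = 0.05
    gsea_p_cutoff: float = 0.05
    diffusion_beta: float = 0.5
    n_permutations: int = 1000
    baseline_heat: float = 0.0
    min_module_size: int = 5
    max_module_iterations: int = 10
    consensus_cutoff: int = 2
    diamond_max_nodes: int = 200
    diamond_alpha: int = 10
    string_confidence_cutoff: float = 700.0
    train_fraction: float = 0.70
    cv_folds: int = 5
    proximity_null_draws: int = 1000
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("extreme_quantile", "drug_extreme_fraction",
                     "gene_min_fraction", "scg_top_quantile",
                     "diffusion_beta", "train_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1); got {v}")
        for name in ("min_samples_per_drug", "n_permutations",
                     "min_module_size", "max_module_iterations",
                     "consensus_cutoff", "diamond_max_nodes",
                     "diamond_alpha", "cv_folds", "proximity_null_draws"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ValueError(f"{name} must be a positive integer; got {v}")

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))


def load_config(path: str | Path | None = None, **overrides) -> AnalysisConfig:
    """Build a config from an optional YAML file plus keyword overrides."""
    fields = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(AnalysisConfig)}
        unknown = set(loaded) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        fields.update(loaded)
    fields.update(overrides)
    return AnalysisConfig(**fields)
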