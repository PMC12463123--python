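# netaml

Network-refined gene signatures for ex vivo drug-sensitivity prediction.

`netaml` is a pipeline for cohorts — typically acute myeloid leukemia
(AML) — profiled with both bulk RNA-seq and ex vivo drug screens. From a
gene × sample expression matrix and a drug × sample matrix of dose–response
AUCs it builds, per drug:

1. **Sensitivity-correlated genes (SCGs).** Spearman correlations ρ between
   each gene's expression and the drug's AUC are variance-stabilized with
   Fisher's transformation, z = atanh(ρ)·√(n−3). Genes with z > 3.7 are
   called positively correlated (PCGs: high expression → high AUC →
   resistance) and genes with z < −4.0 negatively correlated (NCGs);
   a top-5% quantile mode is also available.
2. **Pathway retention.** SCGs are ranked by ρ and tested for pathway
   enrichment with a pre-ranked, weighted Kolmogorov–Smirnov running sum;
   SCGs in any pathway enriched at P < 0.05 are kept as module seeds.
3. **Network modules.** Seed heat |z| is spread over a high-confidence
   protein–protein interaction network (STRING-style edges with combined
   score > 700) with the insulated diffusion kernel
   F = β(I − (1−β)W)⁻¹, β = 0.5, W column-stochastic. Strongly connected
   components of the exchanged-heat graph above a permutation-calibrated
   cutoff are tested against 1000 heat permutations, extracted iteratively
   (largest first, at most 10 rounds, minimum size 5) and kept when found
   consistently across repeated runs. Each module is then expanded by
   connectivity significance (hypergeometric tails with seed links
   up-weighted by α = 10, up to 200 added genes on a full interactome).
4. **Per-drug prediction models.** Feature sets {SCGs, module 1, module 2,
   module 1+2} × feature selectors {none, RFE-CV, lasso, tree importance}
   × a registry of regressors are fit on a 70/30 train/test split with
   5-fold CV; the winner maximizes test AUROC of predicted AUC against
   observed AUC binarized at the training median, and is persisted for
   scoring new bulk cohorts or single cells (per-drug min–max transformed
   layer, lower = more sensitive).
5. **Signed sample scores and proximity.** Positive/negative module genes
   (PMGs/NMGs) are scored per sample with a rank-weighted running sum
   (single-sample enrichment), and drug targets T are related to signature
   genes G by the closest-distance network proximity
   d(T,G) = (1/|T|) Σ_{t∈T} min_{g∈G} d(t,g) with a degree-aware
   randomized null yielding a Z-score.

A seeded synthetic-cohort generator (scale-free network with planted
cliques, latent-factor expression modules driving AUC on a right-tailed
0–300 scale, missing measurements) makes every stage testable without any
external download.

## Worked example

```python
from netaml.config import AnalysisConfig
from netaml.pipeline import run_pipeline
from netaml.simulate import simulate_ppi, simulate_cohort

net, cliques = simulate_ppi(300, planted_cliques=(30, 30), seed=1)
cohort = simulate_cohort(net, cliques, n_samples=200, n_drugs=2,
                         module_size=30, effect_rho=0.5, noise_sd=0.5,
                         missing_frac=0.10, seed=1)
cfg = AnalysisConfig(random_seed=1, diamond_max_nodes=5)
result = run_pipeline(cohort.expr, cohort.resp, net, cohort.sets, cfg,
                      drugs=["drug00"])
run = result.drugs["drug00"]
best = run.best.result
print(len(run.retained_scgs), [len(m) for m in run.modules.modules])
print(best.scenario.feature_set, best.scenario.regressor_id,
      round(best.test_auroc, 3), round(best.test_spearman, 3))
```

On this cohort the screen calls 30 SCGs (all 30 planted genes), module
detection returns a single 35-gene module (Jaccard 0.91 to the planted
module), and the winning model reaches test AUROC 0.932 with test Spearman
0.873 — i.e. predicted AUC ranks resistant samples above sensitive ones
and tracks the quantitative response. The PMG single-sample enrichment
correlates with AUC at Pearson r = +0.79 and the NMG score at r = −0.80,
mirroring the signed construction of the module.

The same workflow is available from the shell:

```bash
netaml simulate --out sim/ --seed 1
netaml run --in sim/ --out results/ --seed 1
netaml proximity --ppi sim/ppi.tsv --targets t.tsv --signature g.tsv \
    --seed 1 --out prox.tsv
```

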