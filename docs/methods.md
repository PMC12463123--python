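# Methods

## Cohort quality control

The extreme-response threshold is the 95th percentile (linear-interpolation
quantile) of the pooled non-missing AUC distribution, computed on the raw
matrix before any exclusion. Filters run samples → drugs → genes: a sample
falls when *every* measured AUC strictly exceeds the threshold (or it has
no measurements); a drug falls when strictly more than 90% of its measured
AUCs strictly exceed the threshold, or when it was screened in fewer than
35 samples (counted after sample removal); a gene survives when its raw
count strictly exceeds 1 in at least ⌈0.10·n⌉ samples. "Exceeding" is read
as a strict inequality throughout, and fractions are taken over non-missing
entries only. Each filter is idempotent, and the report records exactly one
primary reason per dropped item.

## Correlation screen

Spearman ρ is computed per (drug, gene) over pairwise-complete samples
(ranked with average ties, then product–moment on the ranks); p-values use
the t approximation, and Benjamini–Hochberg q-values are attached per drug
across its genes. Fisher's transformation z = atanh(ρ)·√(n−3) puts
correlations at different sample sizes on one approximately standard-normal
scale. Fixed-mode SCG calling uses the asymmetric published-style cutoffs
(z > 3.7 for PCGs, z < −4.0 for NCGs), both exposed independently;
quantile mode instead calls the top 5% of positive-z and of negative-z
pairs over the pooled table. A correlation of exactly ±1 maps to a signed
infinity sentinel and is classified by sign; constant genes yield missing
rows that can never become SCGs.

Expression enters the screen through the normalized layer. When only raw
counts are supplied the layer defaults to log2(CPM+1); Spearman statistics
are invariant to this monotone choice, but it is fixed so that downstream
model coefficients are reproducible.

## Pathway retention

For each drug all genes are ranked by signed ρ and each gene set is scored
with the weighted running-sum enrichment statistic (exponent 1 on |score|;
exponent 0 recovers the classical unweighted KS statistic, for which the
set/complement antisymmetry holds and is tested by enumeration).
Significance comes from seeded gene-label permutations — sample
permutation is not available for a pre-ranked list — with the add-one rule
applied within same-sign null scores, and NES = ES / mean |same-sign null
ES|. SCGs belonging to any set with p < 0.05 are retained as module seeds.
When no set is enriched the SCGs pass through unfiltered with a logged
flag, so a small cohort cannot dead-end the pipeline; this fallback is a
package choice for robustness, not a claim about the original workflow.
The synthetic gene-set collections store the planted positive- and
negative-loading halves as separate sets, since a signed ranking would
cancel a set containing both.

## Network modules

Seed heat is |z| of each retained SCG; all other nodes carry baseline heat
0 so unscored genes cannot seed a module. The diffusion kernel is
F = β(I − (1−β)W)⁻¹ with W the column-normalized adjacency and β = 0.5
(the insulation parameter controlling how far heat spreads; isolated nodes
keep their own heat). Columns of F are random-walk-with-restart
distributions, hence sum to one.

The exchanged-heat matrix E = F·diag(h) defines a directed graph on edges
E_ij > δ. The cutoff δ is data-driven: the median, over random
permutations of the heat assignment, of the smallest cutoff at which
permuted heat no longer yields a strongly connected component of the
minimum module size (5). This calibration-on-permutations rule was chosen
over picking the largest cutoff that still admits a minimum-size observed
component: the latter by construction returns a bare-minimum-size
component whose size statistic the permutation null reproduces (measured
P ≈ 0.10 on the planted-clique fixture), i.e. it has essentially no power
and cannot recover a planted module whole.

Candidate modules are strongly connected components of size ≥ 5 at δ. The
largest is retained when significant at P ≤ 0.05 under a permutation test
on connectivity strength: a permuted heat assignment counts as at least as
extreme when it admits a component of the observed size whose weakest
internal exchanged heat matches or exceeds that of the observed component.
This statistic uses both the size and the edge strength of the observed
component, which is what distinguishes a planted clique from an equally
large but loosely connected arrangement of random hot nodes. The retained
module's genes are removed and the analysis reruns, up to 10 iterations or
until the retained module is at the minimum size. The full iterative
procedure is repeated (consensus parameter, default 2 runs with
independent permutation seeds) and a module is reported only when every
run contains a Jaccard ≥ 0.5 match; reported modules are ordered by
decreasing size with a summed-heat tie-break.

Each reported module is expanded by connectivity significance: at every
step the neighboring gene with the smallest hypergeometric tail
probability of its links into the module joins it, with links to the
original seed genes counted α = 10 times (population, draw and success
counts re-weighted accordingly). Tail probabilities are evaluated in exact
integer arithmetic with one final correctly-rounded division, so the
smallest-p / larger-degree / lexicographic tie chain is decided on true
values. Expansion genes inherit the majority sign of their seed neighbors
(ties → positive), a labeling convention the package fixes because signed
labels are needed downstream and expansion genes have none of their own.
By default expansion runs per detected module; a flag expands the raw seed
list instead.

## Model selection

Feature sets are {SCG, M1, M2, M1+2} (M2 and the union only when a second
module exists). Selectors are {none, RFE-CV (ridge base learner, Spearman
scoring), lasso support at a CV-chosen penalty, random-forest importance
above the mean}; a selector that keeps nothing falls back to the best
univariate feature so the grid never fits on an empty set. The shipped
regressor registry holds 14 mostly linear-family learners (OLS, two ridge
penalties, two lasso penalties, elastic net, Huber, Theil–Sen, Bayesian
ridge, 2-component PLS, linear SVR, k-NN baseline, random forest, gradient
boosting); the registry is configuration, and callers may supply their
own mapping to grow the grid.

Cohorts split 70/30 (seeded, floor on the train size); cv-Spearman is the
Spearman correlation of 5-fold out-of-fold predictions on the training
side. Test AUROC treats the predicted AUC as a score for the "resistant"
class, defined as observed AUC above the training-set median — the
package's explicit binarization convention, with "sensitive" always
mapped to low AUC (a smaller area under the dose–response curve means
more cell killing). The winner maximizes test AUROC with ties broken by
cv-Spearman, then parsimony (fewer selected genes), then registry order.
Failed fits are recorded, never fatal, so failures plus successes always
equal the grid size. The persisted winner carries the fitted predictor,
per-gene training means (imputation fill for genes absent at prediction
time; predictions with more than half the genes imputed are flagged
low-coverage) and the binarization threshold. Cell-level scoring applies
the bulk predictor per cell and adds a per-drug min–max layer on [0, 1].

## Sample scoring

PMGs and NMGs are scored separately per sample with a rank-weighted
running sum: genes are ordered by expression within the sample, hits
accumulate rank^τ with τ = 0.25 (the conventional single-sample exponent;
configurable), misses accumulate uniformly, and the score is the summed
difference of the two cumulative distributions. At τ = 0 the score is a
pure rank statistic, invariant under monotone transforms of expression.
Cohort-level validity is assessed by the Pearson correlation of the
enrichment scores with the drug's AUC.

## Network proximity

d(T,G) = (1/|T|) Σ_t min_g d(t,g) over unweighted shortest paths
(confidence weights are ignored for distances — the statistic counts
hops); a multi-source BFS from the signature set gives every target its
distance in one pass. Unreachable targets are excluded from the mean with
a logged count. The null redraws each target and signature gene from its
log2-degree bin (bins under 10 nodes merge upward; a uniform null is
available by flag), z = (d − μ_null)/σ_null and the empirical p uses the
add-one rule over null draws at or below d. A degenerate null (σ = 0)
flags z and still reports p.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes: a
preferential-attachment (scale-free) network with planted cliques recorded
as ground truth; Gaussian log-scale expression around per-gene baselines;
per-clique latent factors shared by module genes (half loading positively,
half negatively, so PCG/NCG and PMG/NMG classes all exist); drug AUC as a
monotone map of factor + noise onto [0, 300] with the top 5% stretched
toward the ceiling so the extreme-value QC rule is exercised; uniform
missingness. The loading is solved from the requested marginal gene–AUC
correlation (default |ρ| = 0.5 at noise sd 0.5, a realistically strong
pharmacogenomic effect). Defaults follow the cohort structure the pipeline
targets: 200 samples, 30-gene modules, 10% missing measurements, AUC scale
300. What the generator does *not* model — library-size and dispersion
structure of real RNA-seq counts, batch effects, correlated missingness,
multi-pathway polygenic drug response — bounds what passing tests show:
they demonstrate correct mechanics and recovery under the assumed model,
not performance on real cohorts.

Problem sizes used by the test suite and the acceptance script are scaled
to a 300-node network (the analysis is O(n³) in the diffusion step), and
the expansion budget is scaled with it: 200 added genes is calibrated to a
full interactome of ~17k proteins, so the desk-scale configuration caps
expansion at 5 genes. All generators are pure functions of their arguments
including the seed.

## Known limitations

* The module-significance test (connectivity strength at the observed
  size) and the per-module expansion default are package choices where the
  upstream methodology is underspecified; both are exposed in the API.
* Per-sample enrichment significance (when needed) uses gene-label
  permutation, a convention choice.
* The regressor registry is deliberately small and fixed-hyperparameter;
  it is a model-selection surface, not an AutoML system.
* The 628-scenario figure sometimes quoted for grids of this shape does
  not factor as 39 × 4 × 4; grid size here is whatever the configured
  registry implies.
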