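# Methods

This note records the models the package implements, the defaults it
chooses where the procedure leaves them open, and what the synthetic data
do and do not establish.

## Enrichment statistics

`fisher_exact` reports the two-sided exact p (sum of noncentral-free
hypergeometric probabilities ≤ that of the observed table, via
`scipy.stats.fisher_exact`) together with the **conditional-MLE odds
ratio**: the ψ solving E[a | ψ, margins] = a under the noncentral
hypergeometric distribution. We use the conditional MLE rather than the
sample cross-product ratio because it is the estimate conventionally
reported alongside an exact test (e.g. R's `fisher.test`); on the
cluster-vs-nodal table [[9,12],[1,31]] the conditional MLE is 21.81 where
the cross-product ratio would be 23.25. The root-solve is bracketed
bisection on log ψ to 1e-8 with all hypergeometric terms in log space;
when the observed count sits at the boundary of its support the MLE is 0
or +∞, and a zero margin leaves the OR undefined (p = 1). Tests
cross-check the solver against `scipy.stats.contingency.odds_ratio`
(kind="conditional") and against exhaustive enumeration of the support.

Differential expression uses the Welch (unequal-variance) *t*-test —
the procedure is described only as a "t-test", and unequal variances are
the safe default for expression data. Expression is handled as
log2(x + 1); the fold-change between groups is 2^(Δ mean log2), folded so
FC ≥ 1, with default thresholds FC > 1.5 and BH FDR < 0.01. Genes with
zero variance in both groups are excluded with a warning rather than
carrying undefined *t* statistics. BH q-values come from
`statsmodels.multipletests` and are checked against the direct
min-over-tail formula.

Mutual information is the plug-in estimate (nats) from the joint
empirical distribution (`sklearn.metrics.mutual_info_score`).

## Signature derivation

The iteration alternates complete-linkage agglomerative clustering of
samples with DEG calling between the two clusters, starting from the
top-1000 genes with variance > 1.0, and stops when both the DEG set and
the unordered sample bipartition repeat (or at `max_iter = 20` with a
warning). Two open choices:

- **Distance metric.** Unstated in the source procedure; we default to
  1 − Pearson correlation across genes, the common choice for expression
  heatmaps, with Euclidean available. Genes are not standardized before
  clustering by default (`standardize=False` exposed).
- **Singleton clusters.** If the k = 2 cut isolates a single sample, we
  cut deeper until two clusters of size ≥ 2 exist and reassign every
  sample to the nearer (mean-distance) of the two largest — a pragmatic
  rescue that keeps the DEG step well-posed; a warning is emitted.

Cluster orientation follows the predominant histology: the cluster with
the higher fraction of AC/PAP/MP/SOL samples is invasive; an exact tie is
refused. `exclude_genes` removes an arbitrary set (e.g. a proliferation
signature) from every candidate list, replicating the
confound-robustness check in which re-clustering without proliferation
genes reproduces the original partition.

## Invasiveness Score

The elastic net is parameterized as in glmnet: mean loss plus
λ Σ((1−α)/2 βⱼ² + α|βⱼ|), α = 0.02 and λ = 0.1 by default (the published
cross-validated values; a CV mode with seeded folds can re-select λ).
Although the printed objective is squared-error, the score is used as a
"predicted probability", so the default loss family is **logistic**
(probability-native, inverse-logit scores); the squared family with
predictions clipped into [0, 1] is available to match the printed
objective literally. Mapping onto scikit-learn: `l1_ratio = α` and
`C = 1/(n λ)` for `LogisticRegression(saga)`; `ElasticNet(alpha=λ,
l1_ratio=α)` for the squared family. Solver tolerances (1e-8) keep the
final objective within 1e-6 of an independent proximal-gradient oracle on
small problems (asserted in tests).

Both training and test matrices are z-transformed **per cohort**
(population sd, ddof = 0; sample-sd configurable), which absorbs platform
differences; a frozen-parameter mode would be needed for prospective
single-sample use and is out of scope. Scoring matches genes by
identifier; model genes missing from a cohort are dropped from the linear
predictor (error below 50% overlap).

Trichotomization histograms scores into 40 bins of width 0.025 on [0, 1]
(last bin closed). A bin run is a local minimum when both flanks are ≥ the
run's count with one strictly greater; plateaus collapse to their leftmost
bin, and runs touching either end are ineligible. Thresholds are the left
edge of the first minimum and the right edge of the last; classification
is strict (< lower → indolent, > upper → invasive). With no interior
minimum (unimodal scores) the fallback is fixed cutoffs 1/3 and 2/3 with
a warning — fixed-cutoff schemes are a legitimate published alternative.

Survival association fits `lifelines` Cox proportional hazards on
age + sex + stage (or histology) + IVS with administrative censoring at
60 months before Kaplan–Meier/log-rank; the likelihood-ratio p and the
IVS coefficient with its CI are reported.

## Causal network

- **Discretization.** Deterministic 1-D Lloyd k-means (quantile
  initialization), k = 3, clusters ordered by center, cutpoints at
  adjacent-center midpoints. This approximates "biologically meaningful
  cutoffs"; user-supplied cutpoints can override. Constant genes collapse
  to one state.
- **Cis anchoring.** Per-gene slope test of expression on the gene's own
  CNV / methylation value, BH per data type, flags at q < 0.01. Flagged
  genes receive parentless cis root variables (their discretized cis
  feature) that are *permanent* parents of their own gene only —
  cross-gene cis edges are disallowed. This is what breaks the likelihood
  equivalence between X→Y and Y→X.
- **Sparse candidates.** Per-target MI ranking (the global-ranking
  alternative is ambiguous in the source; per-target is implemented),
  dropping the bottom 20%: each candidate set keeps
  ⌊(n−1)·0.8⌋ genes, ties broken by identifier order.
- **Scoring.** BDeu marginal likelihood with equivalent sample size 1.0
  and a per-gene-parent log-penalty of 1.0 (structure prior); these
  hyperparameters are declared defaults, not inferred from the source,
  which names none. Maximum 3 gene parents per node (configurable) bounds
  family enumeration.
- **Search.** Metropolis–Hastings with add/delete/reverse single-edge
  proposals restricted to candidate sets, acyclicity checked by DFS
  before any addition/reversal. Each chain starts empty and returns its
  best structure visited. "Posterior probabilities > 0.3 among candidate
  structures" is operationalized as the strict edge frequency across the
  per-chain best structures (one candidate structure per chain; 1000
  chains by default, scaled down in tests).
- **Cycle removal.** Cycles are found by DFS from the lexicographically
  smallest node with sorted successor order (so the procedure is
  reproducible); each cycle loses its minimum-frequency edge, frequency
  ties broken by the lexicographically smallest edge; removals are logged
  on the result.

## Key drivers

Neighborhoods default to **downstream** (directed descendants), since
drivers regulate their targets in a causal DAG; undirected mode is
provided because the source does not state the choice. The seed is
included in its own neighborhood. The Fisher universe is the set of
network genes, not the genome. "Adjusting multiple testing" is realized
as the fixed 10⁻⁸ threshold; a Bonferroni mode (0.05/nodes) would be a
one-line change in the caller. The greedy scan and the enrichment test
are verified against a brute-force re-implementation on networks up to
100 nodes.

## Synthetic data

`generate_cohort` emits log2-scale expression as baseline (uniform 2–9)
plus per-gene biological noise (sd uniform 0.6–1.1, so variable genes
clear the variance > 1 filter) plus white noise (sd 0.5), with: 60 of 500
genes carrying a ±1.5-log2 class effect (half up, half down); 30 genes
loading 0.8 on a latent proliferation factor drawn independently of
class (enabling the confound-robustness experiment); cis-CNV (25% of
genes, slope 0.8 on a segment-mean-like N(0, 0.5) feature) and
cis-methylation (10%, negative slope on a beta-like feature); histology
drawn class-conditionally so aggressive subtypes concentrate in the
invasive class; nodal positivity at 45% vs 3%; exponential survival with
baseline hazard 0.02/month and class log-HR 1.0 under ~20% random
censoring. The default two-class size 25 + 25 mirrors the scale of the
motivating 53-tumor cohort.

`generate_dag_data` samples a random DAG by ordered edge sampling and
generates 3-state multinomial data where a child copies the rounded mean
of its parents' states with probability `strength` (default 0.85) and is
uniform otherwise; optional cis anchors influence their node the same
way.

What the generator does **not** emulate: negative-binomial read-count
noise, gene–gene correlation beyond the planted blocks, copy-number
segmentation structure, batch effects, or realistic histology–survival
interplay beyond the class effect. Passing recovery tests therefore shows
the algorithms are correctly implemented and statistically sound at these
effect sizes, not that real cohorts of this size would yield equally
clean signatures or networks.

## Problem sizes in the test and acceptance suites

The exact-posterior check enumerates all 25 three-node DAGs and compares
edge frequencies across 200 chains × 150 steps against exact posteriors,
averaged over 20 dataset seeds (mean Spearman asserted ≥ 0.8; individual
seeds fluctuate with tie structure among the six directed edges).
Recovery tests use 500-gene / 50-sample cohorts for the signature, an
80-sample held-out cohort for the IVS AUC, 50 replicates of n = 300 for
Cox CI coverage, 20-node DAGs with 50 chains × 2000 steps for network F1,
and 8-node DAGs over 20 paired seeds for the cis-orientation comparison.
These sizes were chosen so each property is measured with comfortable
statistical margin while the whole suite runs in well under a minute of
compute for the network components.

## Known limitations

- The MCMC proposal is treated as symmetric in the acceptance ratio; for
  returning the best-visited structure (the quantity used downstream)
  this is immaterial, but the chain is not an exact posterior sampler.
- The BDeu equivalent sample size and parent penalty are fixed defaults;
  edge recovery at other settings is untested.
- The squared-loss IVS family clips predictions into [0, 1] rather than
  calibrating them; whether the original analysis clipped or calibrated
  is unstated, so both behaviors are explicit modes.
- Fisher variants (mid-p, one-sided reporting conventions, stratified
  tests) are out of scope.
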