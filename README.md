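# invnet

Tools for dissecting tumor invasiveness in early-stage lung adenocarcinoma
(esLUAD) expression cohorts — for computational biologists studying why some
stage I–II adenocarcinomas (micropapillary, solid, acinar, papillary) invade
and metastasize while others (adenocarcinoma in situ, minimally invasive,
lepidic-predominant) remain indolent.

The package implements four connected analyses:

1. **Invasiveness signature** (`invnet.signature`). Samples are clustered
   (complete-linkage, 1 − Pearson distance) on the top-1000 most-varying
   genes (variance > 1.0), differentially expressed genes between the two
   clusters are called by Welch *t*-test (FC > 1.5, BH FDR < 0.01), and the
   loop *cluster → DEG → re-cluster* is iterated to a fixed point. The
   cluster dominated by aggressive histologies is labeled invasive; DEGs up
   in it are the *pro-invasive* signature, the rest the *indolence*
   signature.
2. **Invasiveness Score** (`invnet.ivs`). An elastic net
   (glmnet convention, mixing α = 0.02, penalty λ = 0.1) is trained on
   z-transformed signature-gene expression against the binary cluster
   labels; the predicted probability in [0, 1] is the IVS. Cohorts are
   trichotomized into indolent / intermediate / invasive at the smallest
   and largest local minima of a 40-bin score histogram, and classes are
   related to outcome by Cox regression
   (`Survival ~ age + sex + stage + IVS`) and log-rank testing with
   administrative censoring at 5 years.
3. **Cis-anchored Bayesian causal network** (`invnet.network`). Expression
   is discretized into low/normal/high by per-gene 1-D k-means (k = 3);
   genes whose expression associates with their own copy number or promoter
   methylation (slope test, FDR < 0.01) get parentless *cis root* anchors;
   candidate regulators are pruned by mutual information (bottom 20%
   excluded); many independent Metropolis–Hastings chains search DAG space
   under a BDeu score; edges in > 30% of the per-chain best structures form
   the consensus network, and residual cycles are broken at their
   weakest-frequency link. Cis anchors make p(X→Y|D) and p(Y→X|D)
   inequivalent, so edges between anchored genes can be oriented.
4. **Key-driver analysis** (`invnet.drivers`). Each node's 2-step
   neighborhood is Fisher-tested against a signature over the network-gene
   universe (default p < 10⁻⁸); drivers are picked greedily, excluding each
   winner's neighborhood from later candidates. Signature-induced connected
   subnetworks are extracted for downstream annotation.

Enrichment statistics throughout use Fisher's exact test with the
**conditional-MLE odds ratio** (the ψ maximizing the noncentral
hypergeometric likelihood with fixed margins — the convention matching
odds ratios reported alongside exact tests), available directly as
`invnet.stats.fisher_exact`.

A seeded synthetic-cohort generator (`invnet.simulate`) provides
ground-truthed multi-omics data — planted signature genes, a proliferation
confound, cis effects, class-dependent survival, and known regulatory DAGs
— so every stage is testable without external cohorts.

## Worked example

The `invnet` CLI chains the stages on TSV matrices (genes × samples,
provenance-commented). On a synthetic cohort:

```sh
invnet --seed 7 --out-dir demo simulate
# wrote synthetic cohort (500 genes x 50 samples) to demo
invnet --seed 7 --out-dir demo signature \
    --expr demo/expression.tsv --annotations demo/annotations.tsv
# signature: 29 pro-invasive, 27 indolence genes (4 iterations)
invnet --seed 7 --out-dir demo ivs \
    --expr demo/expression.tsv --signature-json demo/signature.json \
    --clusters demo/clusters.tsv --annotations demo/annotations.tsv
# classes: {'indolent': 24, 'intermediate': 1, 'invasive': 25}
invnet --seed 7 --out-dir demo network \
    --expr demo/expression.tsv --cnv demo/cnv.tsv \
    --methyl demo/methylation.tsv --n-genes 30 --n-chains 50 --n-steps 1000
# consensus network: 43 nodes, 18 edges (acyclic=True)
```

The signature step converges in 4 rounds and recovers the planted
signature; `ivs_summary.json` reports the Cox fit for the scored cohort
(here `log_hr_ivs = 0.87`, log-rank p = 0.006 across the three classes,
against a planted class log-HR of 1.0). The 2×2 enrichment helper
reproduces the published cluster-vs-nodal-stage association:

```sh
invnet enrich --counts 9 12 1 31
# OR = 21.81    p = 0.0005005
```

meaning node-positive tumors are ~22× enriched (conditional-MLE odds
ratio) in the invasive cluster. Key-driver analysis needs a network with
signature-enriched hubs; on a 50-node toy network with one such hub:

```python
>>> from invnet import key_driver_analysis
>>> key_driver_analysis(g, signature, p_thresh=1e-4)
[KeyDriver(gene='n0', p=5.1e-09, odds_ratio=inf,
           neighborhood_size=26, overlap=20, rank=1)]
```

Library entry points mirror the CLI: `derive_signature`,
`train_ivs_model` / `score_ivs` / `trichotomize` / `survival_association`,
`reconstruct_network`, `key_driver_analysis`, `generate_cohort`.

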