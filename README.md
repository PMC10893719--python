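# igansub

Functional molecular subtyping of case/control expression cohorts, built
around the analysis design used for IgA nephropathy (IgAN) — a common
glomerulonephritis whose clinical grading is histological and whose
molecular heterogeneity is largely uncharacterized.  Starting from a
gene × sample log2 expression matrix, the package:

1. collapses probes to genes (median rule), removes batch location/scale
   effects, and screens **global DEGs** (case vs control, Welch *t*,
   Benjamini–Hochberg, adjusted *p* < 0.05 and |log2FC| > 1.7);
2. discovers *k* **molecular subtypes** among the cases by a
   three-algorithm vote — Ward hierarchical clustering, PAM *k*-medoids
   and Monti consensus clustering on the z-scored DEG submatrix — with
   *k* chosen by majority among the gap statistic, mean silhouette and
   the consensus-CDF delta-area rule, labels harmonized by Hungarian
   matching, and a sample assigned a subtype iff ≥ 2 of the 3 algorithms
   agree;
3. trains a **single-sample random-forest classifier** (features = global
   DEGs, stratified 3:1 split, OOB-driven grid selection of
   `mtry`/`ntree`, one-vs-rest ROC AUC, stratified 5-fold CV);
4. characterizes subtypes via **subtype-specific genes** (intersection of
   global DEGs with subtype-vs-rest DEGs at per-subtype thresholds),
   gene–clinical-trait Pearson correlation, an **expression-bias pathway
   activity score** — per gene *z* = (mean_case − mean_ctrl)/SD_ctrl, per
   pathway the mean |*z*| — with cross-subtype ANOVA, hypergeometric
   over-representation and pre-ranked GSEA;
5. builds a **weighted co-expression network** (unsigned adjacency
   a_ij = |cor(x_i, x_j)|^β, scale-free soft-threshold fit, topological
   overlap matrix, average-linkage modules ≥ 30 genes, eigengene merging
   at correlation 0.75, module–trait correlation, hub genes at |MM| > 0.7
   and |GS| > 0.2);
6. estimates **immune-cell fractions** by nonnegative least squares
   against a signature matrix, with Kruskal–Wallis/rank-sum group tests
   and cell–cell correlations.

A synthetic-cohort generator with exact ground truth (planted subtype
blocks, batches, pathway sets, cell mixtures, clinical traits) makes
every stage testable end to end without any external data.

## Worked example

```bash
python examples/03_subtype_discovery.py
```

```
optimal k: gap=3 silhouette=3 cdf=3 -> majority 3
assigned 90/90 cases (0 unassigned by the 2-of-3 vote)
adjusted Rand index vs planted truth: 1.000
```

On a planted cohort of 90 cases / 12 controls with three equally sized
subtypes (effect 3 log2 units, noise SD 1), all three model-selection
criteria identify *k* = 3, the 2-of-3 vote assigns every case, and the
adjusted Rand index of 1.0 means the recovered partition equals the
planted one exactly.  The other scripts in `examples/` walk through each
capability the same way — e.g. `04_single_sample_classifier.py` prints

```
selected mtry=9, ntree=100, OOB error 0.00%
test accuracy 100.00%; per-class AUC {1: 1.0, 2: 1.0, 3: 1.0}; macro AUC 1.0000
5-fold CV accuracy 100.00%
```

and `06_coexpression_modules.py` shows the three planted 50-gene blocks
emerging as three pure modules whose eigengenes correlate most strongly
with their own subtype's indicator.  `08_full_pipeline.py` runs every
stage from one `RunConfig` and writes a manifest with parameters, derived
stage seeds and output hashes, so identical configs reproduce identical
files.

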