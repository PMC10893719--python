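# Methods

This note records the models, parameter choices and numerical conventions
behind `igansub`, and what the synthetic benchmarks do and do not
demonstrate.

## The synthetic cohort

The generator (`igansub.simulate`) emulates a merged two-batch microarray
case/control cohort on the log2 intensity scale.  Baseline gene means are
drawn N(7, 1.5²) — the typical dynamic range of bead-array intensities —
with i.i.d. Gaussian measurement noise (`noise_sd`, default 1 log2 unit);
no count model is used, since the target data type is microarray.
Defaults mirror the cohort the pipeline was designed around: 107 cases,
14 controls, three subtypes of equal prevalence, two batches.

Planted structure:

* **Global DE block** (default 60 genes): shifted by `effect_size`
  (default 3) in every case; 13% up, 87% down, mimicking the strong
  down-regulation bias of real case/control screens in this disease.
* **Subtype blocks** (default 50 genes each, disjoint): shifted by the
  full `effect_size` in the owning subtype's cases *and* by
  `0.5 · effect_size` case-wide.  The case-wide component is a deliberate
  design choice: subtype markers in real cohorts are also disease
  markers, and the downstream definition of subtype-specific genes — the
  intersection of global DEGs with subtype-vs-rest DEGs — has empty
  support without it.  Both components scale with `effect_size`, so
  `effect_size = 0` is an exact null.
* **Subtype allocation** uses largest-remainder rounding (deterministic
  counts) with round-robin interleaving over case indices, so the
  contiguous batch assignment spans all subtypes as well as both groups;
  batch is confounded with neither.
* **Batch offsets** are drawn per gene per batch (`batch_shift_sd`,
  default 0.5).
* **Clinical traits** (eGFR-like, proteinuria-like) are linear
  combinations of three genes from the first/last subtype block plus
  noise, with coefficients signed to match each gene's planted direction
  so the loadings reinforce.
* **Cell mixtures**: flat-Dirichlet fractions through a marker-structured
  nonnegative signature, plus clipped Gaussian noise.
* `generate_modular_expression` builds hub-structured co-expression data
  (one latent factor per module, memberships decaying linearly from 0.95
  to 0.3) — the construct needed to exercise the scale-free fit, since
  equal-membership blocks produce a two-clump, non-scale-free degree
  distribution.

What passing on these cohorts does *not* show: robustness to probe-level
artifacts, intensity-dependent variance, non-Gaussian outliers, partial
or overlapping subtype membership, or correlated background genes — all
present in real arrays and all absent here by design.

## Preprocessing

Probe collapse keeps only probes mapping to exactly one gene and takes
the per-sample median over a gene's probes.  Batch adjustment is an exact
per-gene location-scale standardization within each batch, restoring the
gene's pooled mean and SD afterwards; it removes additive and
multiplicative batch offsets deterministically but lacks the
empirical-Bayes shrinkage that matters for very small batches.  Per-gene
z-scoring (n−1 SD, floor 1e−8 for constant rows, idempotent) is applied
where the analysis is correlation/distance-based (clustering, classifier
features).  Differential screens run on the *unscaled* adjusted matrix:
per-gene scaling destroys the log2FC unit that the |log2FC| cutoffs are
stated in, and the variance filter of the network stage likewise needs
real variances.

## Differential expression

log2FC is a difference of group means (the data are already logged); the
test is Welch's two-sample *t* — exact under the synthetic model and free
of the empirical-Bayes variance moderation used with very small real
cohorts, which is out of scope here.  BH adjustment is a step-up with
cumulative-min monotonization, applied over all tested genes.  Canonical
thresholds: global (0.05, 1.7); subtype-vs-rest (0.01, 2), (0.01, 1.5),
(0.01, 1.2) for subtypes 1–3 — the looser later cutoffs intentionally
balance feature counts and will admit genes from neighbouring blocks
whose true contrast is half the effect; only genuinely null genes are
guaranteed absent.  Sorting ties break on gene id.

## Subtype discovery

All clusterers operate on samples in the z-scored global-DEG feature
space.  PAM is BUILD + SWAP to a local optimum; the seed only breaks ties
among equal-cost moves.  Consensus clustering is Monti-style: 100
resamples of 80% of samples without replacement, Ward inner clusterer,
consensus = co-cluster/co-sample ratio, final labels by average-linkage
on 1 − consensus.  With `sample_frac = 1` the consensus matrix equals the
base partition's co-membership matrix exactly.

*k* selection: (i) gap statistic with B = 50 uniform-over-feature-range
references and the firstSEmax rule; (ii) mean-silhouette maximizer over
PAM labels; (iii) consensus-CDF rule: with A(k) the area under the CDF of
off-diagonal consensus entries, Δ(k) = (A(k) − A(k−1))/A(k−1) for
k > k_min, choose argmax Δ if it exceeds 0.1, else k_min.  The relative
change is undefined at k_min (there is no k_min − 1 area), and the raw
A(k_min) is on a different scale than the Δ values, so the rule treats
k_min as the no-structure default — on a single Gaussian cloud all three
criteria return the smallest admissible k.  The three votes must have a
majority; a three-way disagreement is an error by design rather than a
silent pick.

Harmonization maximizes agreement with a reference labeling via the
Hungarian algorithm on the k × k contingency table; the consensus labels
serve as reference (most stable of the three; any fixed reference gives
the same votes up to global relabeling).  The 2-of-3 vote leaves
three-way disagreements unassigned; unassigned samples are excluded from
classifier training and subtype contrasts (conservative choice, counts
logged).

## Classifier

Features are the global DEGs; the base learner is a standard random
forest with bootstrap OOB scoring.  Grids default to
mtry ∈ {√p, p/10, p/5, 9} and ntree ∈ {100…500}; the OOB-error minimizer
is selected with ties broken toward smaller ntree then smaller mtry.
Evaluation uses class-vote fractions as scores; one-vs-rest AUC follows
the Mann–Whitney convention (ties count ½), so the macro AUC is exactly
the mean of per-class AUCs.  Cross-validation is stratified with
per-fold retuning on the same grids.  The single-sample contract means
prediction consumes one expression vector over the stored feature list.

## Pathway activity

z_g = (mean_case(g) − mean_ctrl(g))/SD_ctrl(g) (n−1 SD, floor 1e−8);
pathway score = mean |z_g| over set genes present in the matrix (absent
genes skipped and counted).  The cross-subtype ANOVA uses the per-gene
|z| values as replicates within each pathway × subtype cell — a single
aggregated score per subtype admits no ANOVA, so the per-gene level is
the only replicated reading; this is an interpretation, and the groups
share the control mean/SD, so on real data the test is approximate.  The
null-calibration test therefore draws independent half-normal replicates.

## Enrichment

ORA is the upper-tail hypergeometric against an explicit universe, exact
by construction (verified against full enumeration on small universes).
Pre-ranked GSEA uses the weighted Kolmogorov–Smirnov running sum (hits
weighted |score|^w normalized to unit sum, default w = 1; misses
−1/(N − m)); significance and NES come from gene-label permutations
matched on the ES sign — sample permutation would need the full matrix,
which the pre-ranked setting does not have.  The ranking statistic for
subtype GSEA is the subtype-vs-rest log2FC (deterministic with respect to
the DEG output).  No GO/KEGG databases are bundled; gene sets are
caller-supplied GMT.

## Co-expression network

Unsigned adjacency a_ij = |cor(x_i, x_j)|^β.  The scale-free fit bins
connectivity into 10 equal-width bins and regresses log10(frequency) on
log10(mean k); the signed fit index is −sign(slope)·R², positive for a
genuinely decaying degree distribution.  β is the smallest power reaching
R² ≥ 0.9, falling back to the argmax with a warning — the planted
block-structured cohorts are two-clump rather than scale-free and
exercise the fallback, which is expected behaviour, while hub-structured
cohorts select small β (typically 3) at R² ≥ 0.9.  The TOM is the
standard unsigned form TOM_ij = (L_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij).

Module detection replaces hybrid dynamic tree cutting with a static cut
of the average-linkage tree on 1 − TOM: among candidate heights (midpoints
between merge heights), choose the ones maximizing the number of branches
of size ≥ 30, and within the *first* contiguous band of such heights take
the top — inside that band branches only accrete peripheral genes, so the
cut captures complete modules just before they agglomerate; later bands
at the same count are loose background agglomerates.  Undersized branches
are grey.  Eigengenes are PC1 of the gene-standardized submatrix, unit
(n−1) variance, sign fixed to correlate nonnegatively with the module's
mean profile.  Merging clusters eigengenes at 1 − cor and collapses
branches below 0.25 into the largest member, iterating to stability;
module count never increases.  Hubs require |MM| > 0.7 *and* |GS| > 0.2,
strict inequalities.  Module colors are a fixed palette ordered by
decreasing size (cosmetic only).

## Deconvolution

Per sample, nonnegative least squares of the shared-gene bulk vector on
the signature columns, renormalized to the simplex; an all-zero solution
falls back to uniform with a warning.  NNLS is deterministic and exact on
noise-free full-rank mixtures; it lacks the robustness of support-vector
regression variants on heavily noisy real mixtures, which is the
trade-off accepted here.  Relative (simplex) fractions only — no absolute
score, no permutation p-value.  Group tests: Kruskal–Wallis across all
groups and Wilcoxon rank-sum per group vs control (exact when both
n ≤ 25 without ties, else normal approximation with continuity; an
explicit asymptotic mode without continuity makes the two-group identity
χ²₁ = z² exact).  BH within each test family; stars bin adjusted p at
0.05/0.01/0.001/0.0001.

## Workflow and reproducibility

`run_pipeline` executes simulate → batch adjust → global DEGs → subtype
discovery → classifier → subtype contrasts/specific genes → traits →
pathway activity → enrichment → network → deconvolution, writing TSVs and
a JSON manifest (parameter block, derived seeds, SHA-256 of each output).
Per-stage seeds derive from the global seed by CRC-32 of the stage name,
kept below 2³¹, so stages rerun identically in isolation.  Problem sizes
in the bundled tests and the acceptance script — 90 cases / 12 controls,
2000 genes, 500 network genes, 100 consensus resamples, 400–500
permutations — were chosen as the smallest cohorts at which every planted
effect is comfortably recoverable and the suite stays quick on one CPU.

## Known limitations

* Batch adjustment is non-EB; very small batches on real data would be
  over-corrected.
* The static module cut cannot recover nested or strongly unbalanced
  module hierarchies the way dynamic tree cutting can.
* The ANOVA replication unit for pathway scores is an interpretation (see
  above).
* Welch *t* has less power than moderated statistics at very small n.
* The classifier's reported AUCs on tiny test sets are high-variance;
  per-class AUC is undefined for classes absent from the test split and
  is then skipped with a warning.
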