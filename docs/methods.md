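# Methods

## Problem setting

Two omics modalities measured over mostly the same tumor samples — an
RNA-seq-style gene expression matrix and a GISTIC2-style gene-level copy
number matrix — each carry partial, complementary information about a binary
cancer subtype (the motivating setting is the adenocarcinoma vs squamous cell
carcinoma distinction in non-small cell lung cancer). Both matrices are in
the high-dimension-low-sample-size regime (thousands of genes, hundreds of
samples). The package implements two connected procedures:

1. **Decision-level (late) fusion.** Train one probabilistic classifier per
   modality and combine their *predicted probabilities* — not their features —
   with weights derived from how well each modality's model fits its training
   split.
2. **Stability gene selection.** Rank genes per modality with ReliefF inside
   cross-validation, keep genes that stay top-ranked across folds, seeds and
   finally across both modalities.

## Harmonization and normalization

Samples are matched across modalities by exact barcode identity (the
hierarchical project–TSS–participant–sample form); only samples present in
both matrices are analyzed. Any missing cell aborts the pipeline (the audit
reports its address). Each modality is z-scored **sample-wise** (each sample
row scaled to mean 0, sd 1) using the population (divide-by-n) convention;
constant rows map to all-zero rows instead of raising, since they carry no
within-sample contrast. Normalization is applied after common-sample
restriction so it sees exactly the analyzed samples.

## Cross-validated benchmarking

Stratified k-fold cross-validation (k = 5) is repeated over several seeds
(default 5). The single fold plan per seed is shared by both modalities, so
fold i's validation samples are identical and identically ordered in both —
the alignment that makes per-sample probability fusion well-defined. Per
fold and modality we record the **train-split accuracy** (using the
validation split here would leak) and the validation samples' class
probabilities. Classifiers are adapters over established implementations at
their default hyperparameters — gradient boosting (xgboost), RBF-kernel SVM
and MLP (scikit-learn) — each receiving the fold seed for its internal
randomness. The bespoke content of this package is the harness, the fusion
rule and the selection pipeline, not the models.

## The fusion rule

With per-fold train accuracies acc_R and acc_C and scaling factor k:

    alpha = |e^(acc_C) − e^(acc_R)| · k
    w_R   = e^(alpha·acc_R) / (e^(alpha·acc_R) + e^(alpha·acc_C)),   w_C = 1 − w_R
    p_F   = w_R · p_R + w_C · p_C          (per class, per validation sample)

The predicted label is the argmax of the fused pair (the max fused *value*
is a probability, not a label); exact probability ties go to class 0, a
deterministic rule whose measurable effect on continuous scores is nil.
Weights are computed **per fold** — train accuracies vary across folds — and
applied to every validation sample of that fold.

Properties that the tests pin down: the weights are a softmax, so they sum
to 1; equal accuracies give alpha = 0 and exact soft voting; w_R > 0.5 iff
acc_R > acc_C; the fused probability is a convex combination of the two
modality probabilities; as k → ∞ the fused output converges to the
more-accurate modality's output. The softmax is evaluated in max-subtracted
form, so accuracies in [0, 1] with k up to 1e6 cannot overflow. The absolute
value bars around the exponentials are dropped: exponentials of validated
in-range inputs are positive. Default k = 10, at the plateau of the
fused-accuracy-vs-k curve (analysis/03 reproduces the sweep on synthetic
data; the curve is flat to ~1e-3 over k = 2…30 when both modalities are
already strong, and the plateau choice matters most when they disagree).

Baselines implemented alongside: equal-weight soft voting (identical to
fusion at alpha = 0), hard voting (majority over the two predicted labels,
1–1 ties falling back to the soft-vote label), and early integration (one
model on the column-concatenated feature matrix with modality-prefixed gene
IDs).

## ReliefF and stability selection

Relief scores an attribute by local class contrast: for an instance, find
its nearest same-class neighbor (hit) and nearest other-class neighbor
(miss) and update W[A] by −diff(A, x, hit)/n + diff(A, x, miss)/n. ReliefF
averages over the k nearest hits and k nearest misses instead, which
stabilizes the weights in noisy high-dimensional data. Choices fixed here:

- diff(A, x, y) = |x_A − y_A| / range_A with ranges from the training split;
  zero-range (constant) attributes contribute 0.
- Neighbor distance is the Manhattan sum of per-attribute diffs; distance
  ties break by sample order, making the procedure fully deterministic.
- Every instance is scored (n_sampled = ALL), so "randomly select an
  instance" becomes a full pass and the weights are a pure function of the
  data. An instance is never its own hit. Weights are then bounded in
  [−1, 1].
- k_neighbors defaults to 100, the customary large-cohort default; it is
  clipped with a warning to (min class size − 1) on small data.

The selection pipeline: per seed, build the stratified fold plan, run
ReliefF on each fold's **train split only** (anti-leakage is tested by
sentinel-poisoning validation rows), sum the per-fold weights per gene into
a cumulative score, sort (score ties break lexicographically by gene ID) and
keep the top N (default 500). Intersect the per-seed top-N sets within each
modality ("stable" sets), then intersect the two stable sets across
modalities for the final panel; the union of the stable sets is kept for the
union-vs-intersection comparison. Set sizes are monotonically non-increasing
along this chain. Cumulative-score aggregation uses raw weight sums, not
rank sums — "cumulative importance" is read as score addition.

## Evaluation

Confusion-matrix metrics (accuracy, precision/PPV, recall/sensitivity,
specificity, F1, NPV) use positive class 1 by default (configurable);
zero-denominator ratios are reported as 0 with an explicit flag rather than
dropping folds, keeping seed aggregation well-defined. AUROC is computed by
mid-ranks (the Mann–Whitney formulation, ties counted ½), which the tests
verify against an independent implementation; for fusion it uses the fused
positive-class probability. Per-seed results aggregate as mean ± population
sd. Group comparisons use the two-sided Mann–Whitney U test (exact null for
groups of ≤ 8 without ties, normal approximation otherwise) with the
rank-biserial effect size 1 − 2U/(n_A·n_B); in this convention the sign is
positive when the first group tends *smaller*. Comparisons can be built from
per-seed (n = 5) or per-fold values; the analysis scripts use per-seed.
Pairwise gene–gene association uses Pearson correlation; constant genes
yield flagged zero entries.

The selected-gene re-evaluation restricts both modalities to the panel,
reruns the identical benchmark + fusion machinery, and reports accuracy and
AUROC per approach. With the full gene set it reproduces the unrestricted
pipeline bit-for-bit under identical seeds.

## The synthetic cohort generator

The generator exists so every downstream stage has a ground truth. Each gene
is standard normal within class; genes are grouped into equicorrelated
blocks (shared Gaussian factor, default block size 10, rho 0.3); an
informative gene shifts its class-1 mean by the configured effect size in
sigma units, so the planted class-conditional mean difference *is* the
effect size. Planted genes are either shared between modalities (same gene
ID, independent measurement noise, shifted in both) or modality-specific.
Blocks never straddle the informative/noise boundary, keeping the ground
truth unambiguous. Sample IDs follow the 4-field barcode pattern so the
barcode-matching path is exercised; per-modality dropout removes disjoint
sample subsets from one modality only.

Defaults emulate the motivating cohort's shape at desk scale: a 590 + 565
base cohort with dropout fractions 0.025 (expression side) and 0.12
(copy-number side) yields per-modality totals of ~1126/1016 and ~988 common
samples (~505 vs ~483 per class); 2000 genes per modality keep the
genes ≫ samples shape; expression effect 1.5σ vs copy-number 1.0σ encodes
the observation that the two modalities differ in difficulty. Class balance
is near-even by default but fully configurable.

What the generator does **not** emulate: raw read counts and library-size
effects, segmentation artifacts, batch effects, heavy-tailed or discrete
marginals, gene–gene networks beyond equicorrelated blocks, survival or
demographic structure. Passing tests therefore demonstrate correctness of
the machinery and qualitative behavior (fusion gains under complementary
signal, planted-gene recovery), not clinical performance on real cohorts.

## Problem sizes used by the tests and the acceptance script

The recovery study uses 300 samples/class, 1000 genes/modality, 30 shared +
10 + 10 planted genes at 1.5σ/1.0σ, 5 folds × 5 seeds, top-100. The
complementary-signal benchmark uses 150 samples/class, 500 genes, 25
disjoint informative genes per modality at 1.0σ; the null control uses 100
samples/class, 400 genes, no signal. These sizes were fixed once as
realistic desk-scale instances of the respective regimes; the analysis
scripts run the full default cohort instead.

## Known limitations

- Two modalities only; the fusion formulas are written for the binary case.
- Binary labels only; no multi-class Relief variants (SURF/MultiSURF,
  RReliefF) and no iterative feature elimination.
- ReliefF builds the full pairwise distance matrix per fold (O(n²·m)); fine
  for hundreds of samples, not tuned for tens of thousands.
- The Mann–Whitney exact path declines to small *tied* samples (falls back
  to the normal approximation), a scipy constraint.
- No class-imbalance correction; the generator exposes imbalance but the
  pipeline applies no resampling.
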