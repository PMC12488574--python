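# Methods

## Stage-encoded linear models

Expression is modelled gene-wise on the log2 scale over group indicators
(control plus AJCC macro stages I–IV). Because both supported codings —
reference (intercept = control baseline, coefficients = stagewise lfc) and
cell-means (one mean per group) — are group-indicator designs, the
least-squares solution is the vector of group means; the package computes
it in closed form rather than via a generic solver, and the two codings are
algebraically equivalent (`β_k` in reference coding equals `β_k − β₀` in
cell-means coding, balanced or not). Optional per-observation precision
weights (from the variance-stabilization trend) turn the group means into
weighted means.

Gene-wise residual variances are shrunk toward a pooled prior before
t-statistics: a scaled inverse-chi-square prior is fitted by matching the
moments of log s² (digamma/trigamma identities, with a Newton inversion of
the trigamma function), and posterior variances
`(d₀s₀² + d s²)/(d₀ + d)` are used with `d₀ + d` degrees of freedom. When
the observed spread of variances is no larger than sampling noise the
shrinkage degenerates to the common-variance limit (normal reference
distribution). Moderation can be disabled (`moderate=False`), which the
tests use to compare coefficients against a direct group-mean oracle.
Benjamini–Hochberg adjustment is applied within each contrast family
(each stage-vs-control contrast, each inter-stage pair, each group pair),
never pooled across families.

## Two-level contrast protocol

Level I retains, per stage, genes with |lfc| > 2 and BH-adjusted p < 0.001
(strict inequalities on both: a gene at exactly lfc 2 is excluded, and a
gene with sample sd exactly at the variance-filter boundary σ = 1 is
retained upstream). Level II assigns the candidate salient stage by
argmax over |β_k − β₀| — an exact tie yields no call — and confirms it only
if every pairwise inter-stage contrast of the salient stage is significant
at the (configurable, BH-adjusted by default) 0.05 level with deviations of
consistent sign. The reported contrast p is the worst pairwise adjusted p,
and per-stage lists are truncated to the top 10 by that p. This
formalization was chosen because it reproduces, from the bundled published
coefficient table, all 24 printed stage labels and directions.

Monotonic genes require strictly monotone stage means (group means, not
medians); flagged genes get an ordinal regression of per-sample expression
on stage coded 1–4 with controls excluded (the published intercepts are
consistent with a stage-anchored fit), and slope p-values are BH-adjusted
across flagged genes. A *significant* monotonic call additionally requires
adjusted p < 0.05 — strict monotonicity of four noisy means alone occurs in
a non-negligible fraction of null genes (the stage groups have very unequal
sizes, which inflates the chance of a monotone-looking trajectory), and
the significance filter is what brings the null call rate to ~0.

Contra-regulation is specified only loosely in the source material; the
default taxonomy here is: a stage-specific gene is contra-regulated when
its deviation-from-control trajectory changes sign across stages with an
interior extremum — patterns 1–3 are up-anchored extrema at stage I/II/III,
patterns 4–6 their down-anchored mirrors; an extremum at stage IV (terminal
trend) is not paradoxical and yields no call. This is a documented
interpretation, not an asserted reproduction of the original six patterns.

## Preprocessing

* Variance filter: per-gene sample sd ≥ σ_min (default 1) retained.
* Variance stabilization: log2(x + 0.5). The 0.5 pseudo-count avoids −∞
  and closely tracks the standard variance-stabilizing transform for
  rank-based downstream use. Optional weights come from a lowess trend of
  sqrt(sd) against mean log2 expression across genes; each gene's weight
  is trend(mean)⁻⁴, constant within gene — a gene-level approximation of
  observation-level variance weighting that suffices for the group-mean
  fits used here.
* Stratified split: per-stratum largest-remainder rounding so the train
  total equals round(n × fraction) while every stratum stays within one
  sample of the target. The published cohort's own split counts do not
  follow any single rounding rule, so internal consistency, not count
  replication, is the contract. Strata below two samples go wholly to
  train with a warning.
* SMOTE: percentage-based counting semantics — `n_min · perc.over/100`
  synthetic minority points (each a convex combination of a minority point
  and one of its k minority neighbours), majority downsampled to
  `(perc.under/100) · n_min · perc.over/100` without replacement when
  possible. These are the only semantics consistent with the published
  16 → 176 / 837 → 480 counts.
* FSQN: per gene, target values are rank-mapped onto the reference gene's
  empirical quantiles, removing per-gene platform shifts while preserving
  within-gene sample ranks.
* IHC subtyping: triple-negative → TNBC; HER2+ with both hormone
  receptors negative → HER2; any hormone-receptor positivity → Luminal,
  with the A/B split emitted only when a Ki-67 index is available
  (threshold 0.14). Missing receptor states propagate to NA, never imputed.

## Feature selection

Boruta is reimplemented (it is part of the defined computation): each
iteration appends permuted shadow copies of all features, fits a
500-tree random forest, and scores a hit when a real feature's importance
exceeds the maximum shadow importance; hit counts are tested against
Binomial(n, ½) two-sided at α = 0.01, with tentative features excluded by
default and constant features auto-rejected. RFE ranks features by
recursive random-forest elimination and picks, over candidate subset
sizes scored by stratified CV balanced accuracy, the smallest size within
one standard error of the best — a rule that favours the small panels this
kind of pipeline aims for. The final panel is the intersection of the two
selectors (RFE order preserved); an empty intersection falls back to the
RFE set with a warning. Ranking ties are broken by column order for
reproducibility.

## Models and evaluation

Six families with default grids: random forest (250/500 trees, mtry ∈
{√p, p/3}); RBF-SVM (C ∈ {0.1, 1, 10}, γ = scale, standardized inputs);
k-NN (k ∈ {3, 5, 7, 11}); 1-/2-layer MLPs (hidden 8/16/32 per layer, fixed
400-iteration cap — a validation-split early stop is brittle at this
cohort's smallest class sizes); XGBoost (depth {2, 4, 6}, η {0.05, 0.3},
200 rounds). Tuning is stratified 10-fold grid search on balanced accuracy,
refit on the full training set; families are compared on the untouched
holdout (ties broken by MCC, then family order). Probabilities are raw
model scores, uncalibrated. Multiclass metrics: macro-averaged one-vs-rest
sensitivity/specificity/PPV/AUROC and Gorodkin's R_K for the MCC. The
agreement ensemble accepts only unanimous predictions, reports coverage and
accuracy over accepted samples, and abstains otherwise.

The cascade gates the three second-level models on a "cancer" screen call
and never overrides a weak screen call — it annotates it. Confidence
thresholds default to 0.9 (screen), 0.75 (metastasis), 0.7
(subtype/histology), the probability bands observed to separate correct
from incorrect predictions in the published validations; all are
configurable per model.

## Multi-omics concordance

Expression concordance of a (gene, miRNA) pair requires opposite
directions; temporal concordance (evaluated only when expression
concordance holds, otherwise NA) requires the miRNA's salience stage to be
no later than the gene's. Methylation probes of a gene are clustered by
average-linkage on 1 − r, cut at the coarsest level where all
within-cluster pairwise correlations exceed 0.7. Beta distributions are
decomposed by Gaussian mixtures on the logit (M-value) scale for numerical
stability, component count by BIC, means reported back through the
logistic map. Differential methylation uses the rank-sum test with BH
adjustment and a 0.1 effect-size filter on the difference of group mean
betas; drivers additionally require methylation–expression correlation
≤ −0.3 at p < 0.001. The three stage-informed salience routes — probe-mean
betas, logit M-values, and mixture-component posterior means — are each
run through the identical two-level contrast (with methylation-scale
thresholds) and intersected on the salient stage; the "averep" and
"M-value" routes are interpretations of procedures specified only by
citation in the source material. Methylation-before-expression concordance
requires a direction-compatible change (Hyper with expression Down or Hypo
with Up) and methylation salience no later than the expression extremum;
ties count as concordant (configurable in principle; the bundled worked
cases are unaffected either way).

## Synthetic cohort generator

The generator emulates the reference cohort's structure: 112 controls and
181/616/249/20 samples in stages I–IV (so an 80:20 split reproduces the
~16:837 metastasis imbalance), subtype fractions 0.789/0.051/0.160
(Luminal/HER2/TNBC) and histology fractions 0.794/0.206 (IDC/ILC), with
stage IV ⇔ metastatic. Expression noise is Gaussian on the log2 scale —
the pipeline consumes variance-stabilized data, so read-level simulation
would add nothing the downstream math can see. Default planted truth:
per-stage salient genes at |lfc| 4 (the scale of the published salient
coefficients, with off-stage effects at 55% of the salient effect so
inter-stage contrasts are decidable), monotonic genes at slope 0.6/stage,
cancer-wide genes at |lfc| 4.5, one contra gene per pattern, and
subtype/histology/metastasis markers; 1,000 genes in total, the rest null.
The gene count is a desk-scale choice — genome-scale columns would change
runtimes, not the statistical structure the tests probe. A single seed
fans out into independent per-layer substreams, making all three layers
jointly reproducible.

The miRNA layer plants regulators with their own stage-salient profile
plus an anti-correlation term against the target's standardized
expression; the methylation layer draws per-sample latent M-values from
declared mixtures (weights may differ between normal and cancer samples,
planting differential methylation), adds optional stage-salient shifts
and expression-coupling terms, and shares the latent value across a
gene's probes with small probe-level noise.

What the generator does **not** emulate: raw-count mean–variance
structure, batch effects, correlated co-expression modules, copy-number
or mutation layers, and realistic miRNA target multiplicity. Passing
recovery tests therefore demonstrates that the algorithms are correct
under their stated model, not that the pipeline's published cohort-scale
findings transfer to arbitrary real data.

## Numerical choices and degenerate inputs

Exact salience ties yield no call (logged); all-tied methylation rows get
p = 1; zero-variance inputs to correlation give NA, never a driver call;
an empty variance-filter result warns instead of raising; SMOTE reduces k
with a warning when the minority class is smaller than k + 1; mixture
non-convergence falls back to fewer components with a warning. All
stochastic steps take explicit seeds.

## Problem sizes used in the checks

The recovery checks run on the default cohort (1,178 samples × 1,000
genes); the Boruta permutation null uses 6 replicates of 80 × 20 with
reduced forest sizes (the binomial property does not depend on forest
size); mixture recovery uses 50 replicates of n = 300; the end-to-end run
uses the default cohort with reduced selector iterations and grids
(`fast=True`) and completes in a few minutes on one CPU.
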