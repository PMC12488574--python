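# stagemark

Stage-salient biomarker mining and cascade classification for breast-cancer
transcriptomics.

Breast cancer is strongly heterogeneous: a sample's AJCC stage, metastatic
status, molecular subtype (Luminal / HER2+ / TNBC by ER, PgR and HER2
immunohistochemistry), and histology (infiltrating ductal vs lobular
carcinoma) each call for different clinical handling. `stagemark`
implements a complete pipeline for mining stage-informative expression
biomarkers from a control + stage I–IV cohort and turning them into a
cascade of classifiers with an uncertainty readout, together with a
multi-layer synthetic cohort generator so every stage of the pipeline can
be exercised and validated against known ground truth without any data
download.

## What it computes

**Stage-encoded differential expression.** Gene-wise linear models over
group indicators, in two codings:

- reference coding — `y = α + β₁X₁ + β₂X₂ + β₃X₃ + β₄X₄`, where `α` is the
  control baseline and `β_k` the stage-k log2 fold-change (lfc) vs control;
- cell-means coding — `y = β₀X₀ + … + β₄X₄`, one mean per group with the
  controls as one of the indicators.

Gene-wise residual variances are moderated by empirical-Bayes shrinkage
toward a pooled prior before t-statistics; p-values are
Benjamini–Hochberg adjusted within each contrast family. A two-level
contrast protocol then produces the feature classes:

- **level-I (stage vs control)**: stage-specific genes with |lfc| > 2 and
  adjusted p < 0.001 per stage;
- **level-II (inter-stage)**: *stage-salient* genes — the salient stage k
  maximizes |β_k − β₀| and every pairwise stage-k-vs-stage-j contrast is
  significant with consistent sign;
- **monotonic genes** — strictly increasing/decreasing stage means, with
  an ordinal (stage 1–4) regression fit;
- **contra-regulated genes** — trajectories that reverse sign against the
  control baseline (six patterns by anchor position and direction).

**Feature selection and models.** Problem-specific base pools (stage-salient
∪ top linear-model genes; rank-consensus of the metastasis contrast; top
genes per subtype pair; |lfc|-thresholded histology contrast) are reduced by
the consensus of a Boruta-style shadow-feature wrapper and cross-validated
RFE (one-standard-error size rule). Six classifier families (random forest,
RBF-SVM, k-NN, 1- and 2-layer neural networks, XGBoost) are tuned by
stratified 10-fold CV on balanced accuracy and compared on an untouched
holdout (nested selection). The metastasis problem's 16:837 class imbalance
is corrected by SMOTE with percentage-counting semantics
(`perc.over = 1000%`, `perc.under = 300%` maps 16 → 176 and 837 → 480).

**Cascade with uncertainty.** A screening model gates three second-level
models; each prediction carries its probability and a strong/weak flag, the
histology model may be an agreement/abstain ensemble, and the readout is
composed into a phrase such as `Metastatic triple-negative ductal cancer`.

**Multi-omics concordance.** miRNA regulators are mined with the same
two-level protocol; a (miRNA, target) pair is expression-concordant when
directions oppose and temporally concordant when the miRNA salience is at
least as early as the gene's. Methylation beta values are probe-clustered,
decomposed into Gaussian mixtures on the logit scale (component count by
BIC), tested for differential methylation (rank-sum + effect-size filter),
correlated against expression (driver threshold r ≤ −0.3, p < 0.001), and
stage-salience is called by the consensus of three stage-informed routes.

## Worked example

```python
import stagemark as sm

# the published stage-salient coefficient table bundled with the package
ref = sm.load_stage_salient_reference()
row = ref.loc["CST2"]
call = sm.salient_stage_rule(
    row["control_mean"],
    [row["lfc_I"], row["lfc_II"], row["lfc_III"], row["lfc_IV"]])
print(call)            # ('III', 'Up') — stage-III salient, upregulated

# a full synthetic run: simulate -> contrasts -> selection -> models -> cascade
result = sm.run_pipeline(config=sm.CohortConfig(seed=7), seed=7)
print(result.winners)
print(result.summary.head())
```

Printed output from that run:

```
('III', 'Up')
{'screen': 'random_forest', 'metastasis': 'random_forest',
 'molsubtype': 'random_forest', 'histology': 'svm'}
phrase
Non-metastatic luminal ductal cancer            121
Non-metastatic luminal lobular cancer            32
Non-metastatic triple-negative ductal cancer     32
Normal breast tissue                             23
Non-metastatic triple-negative lobular cancer    10
```

`('III', 'Up')` is the salience call recomputed from the printed
coefficients (the deviation 4.22 at stage III is the largest), and the
summary counts the composed cascade readouts over the held-out synthetic
samples — dominated by non-metastatic luminal ductal cancers, as the
planted subtype and histology fractions dictate.

A CLI covers the common entry points:

```sh
stagemark simulate --out cohort/ --seed 1
stagemark dge --expr cohort/expression.tsv --annotation cohort/annotation.tsv --out dge/
stagemark pipeline --out run/ --seed 1
```

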