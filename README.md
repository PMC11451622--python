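# tmepredict

Cell-type-resolved prediction of therapy response from deconvolved tumor
expression.

## The problem

Bulk tumor RNA-seq averages over the tumor microenvironment (TME): malignant
cells, immune cells and stroma all contribute to one expression profile, so
a bulk classifier of treatment response cannot say *which* cell types carry
the signal. Computational deconvolution (e.g. CODEFACS-style tools) breaks a
bulk cohort into per-cell-type expression matrices, a per-gene confidence
score in [0, 1] for each cell type, and per-sample cell fractions.
`tmepredict` models the TME downstream of such output at three levels:

1. **Single cell types** — one response predictor per cell type, so the
   predictive power of, say, myeloid cells vs. malignant cells can be
   compared directly.
2. **Multi-cell-type ensembles** — 2–3 cell types' expression profiles
   appended into one feature space, testing whether compartments carry
   complementary information.
3. **Cell–cell interactions (CCIs)** — quadruplets (ligand cell type,
   ligand gene, receptor cell type, receptor gene) whose binary per-sample
   activity feeds a random-forest classifier, with signed importances
   pointing at the communication channels associated with response.

A synthetic-data module generates single-cell cohorts, deconvolved-cohort
fixtures and pseudobulk benchmarks with *planted, known* structure, so the
entire stack is testable end to end without any external download.

## The model

**Per-cell-type predictor** (four stages, applied to log2(TPM+1) values):

- (a) keep genes deconvolved with confidence ≥ 0.99;
- (b) keep genes with across-sample variance ≥ 0.1;
- (c) rank genes by ANOVA *F* for association with response and keep the top
  *m* (2 ≤ *m* ≤ 25), then standardize each gene to zero mean, unit variance;
- (d) score samples with an unweighted ensemble of four classifiers —
  L2-regularized logistic regression, random forest, RBF-kernel SVM and
  gradient-boosted trees (XGBoost) — averaging their probabilities.

Training uses stratified 3-fold cross-validation repeated 5 times with
distinct splits. Feature ranking and standardization are refit inside each
training fold; *m* and each learner's hyperparameters are chosen by a nested
inner CV, so the out-of-fold scores are unbiased. The five out-of-fold score
vectors are averaged and min–max rescaled to [0, 1]. The bulk baseline skips
stage (a); the cell-fraction baseline skips (a)–(c).

**Interaction arm**: a database of plausible CCIs is curated from single
cells by permutation testing — the observed score of a quadruplet is
(mean ligand expression in the ligand cell type) × (mean receptor expression
in the receptor cell type), the null redistributes cell-type labels, and
quadruplets with empirical *P* ≤ 0.05 are "likely". In a deconvolved cohort a
quadruplet is **active** in a sample iff both ligand and receptor exceed
their cell-type-specific across-sample medians. The binary activity matrix
(variance filter 0.08, random forest, 2 ≤ *m* ≤ all) yields a CCI-based
predictor; two-sided Fisher tests with Benjamini–Hochberg adjustment sign
each CCI by responder enrichment (OR > 1 and FDR ≤ 0.05 ⇒ +1). Top CCIs are
validated in single-cell data by pooling cells per response group,
downsampling 30% per cell type into replicate "pseudopatients", and scoring
each pseudopatient by its signed sum of active CCIs.

**Evaluation**: AUC, average precision, diagnostic odds ratio
DOR = (TP·TN)/(FP·FN) at a PR-optimal (max-F1) threshold with
Haldane–Anscombe correction, one-tailed Wilcoxon rank-sum tests, BH
adjustment, and Kaplan–Meier / log-rank survival stratification at a fixed
0.5 score threshold.

## Worked example

`examples/` contains one short script per capability. For instance,
`python examples/02_celltype_response_predictors.py` builds a 60-patient
synthetic cohort in which ten genes in the (minority) myeloid compartment
are shifted by 1.5 log-units in responders, then trains all predictors:

```
predictor       AUC     AP      DOR
B-cells       0.350  0.405     1.00
myeloid       1.000  1.000  3721.00
T-cells       0.401  0.510     1.00
bulk          0.541  0.562     6.00
fractions     0.490  0.500     1.56
```

The planted myeloid compartment is recovered perfectly (AUC 1.0), the
unplanted cell types and the abundance baseline sit at chance
(AUC ≈ 0.5, DOR ≈ 1), and the bulk mixture — where myeloid cells are ~6% of
the cells — retains only a diluted trace of the signal. The other examples
walk through synthetic-cohort construction, the deconvolution-accuracy
benchmark (Kendall τ, accurate-gene counts), CCI discovery (the planted
ligand→receptor channel ranks first by Gini importance with sign +1), and
pseudopatient validation (signed-CCI score AUC 0.96 on 100 pseudopatients).

A thin CLI mirrors the library: `tmepredict synth | train | predict |
evaluate | benchmark | cci-curate | cci-activity | cci-train`.

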