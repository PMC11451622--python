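# Methods

This note records what `tmepredict` computes, the assumptions behind each
stage, the defaults and why they were chosen, and what the synthetic-data
tests do and do not demonstrate.

## Data model

All cohort objects are thin wrappers over pandas structures. Expression is
stored genes × samples with an explicit scale tag (`tpm` for linear
non-negative values, `log2tpm1` for log2(TPM+1)); samples × features views
are derived on demand and never persisted. Gene identity is the symbol
string, case-sensitive; duplicate gene rows in input tables are collapsed by
their mean (and logged), a neutral choice when the duplicates are
quantification artifacts. Cell-fraction rows must sum to 1 within 1e-3 and
are renormalized exactly; rows already summing to 1 within 1e-12 are left
untouched so exact ties between samples survive renormalization (rank
statistics downstream are sensitive to tie-breaking noise). The reference
TME partition is the nine-cell-type set used for breast tumors (B-cells,
CAFs, malignant, endothelial, myeloid, normal epithelial, plasmablasts,
PVL, T-cells), but nothing restricts cohorts to it.

## The four-stage response predictor

Stages, applied per cell type:

(a) **Confidence prefilter** — keep genes with deconvolution confidence
≥ 0.99 (inclusive). Confidence scores are taken at face value; the stage is
unsupervised and therefore applied once, outside cross-validation.

(b) **Variance filter** — keep genes with across-sample variance ≥ 0.1,
computed on the log2(TPM+1) scale. The threshold is only meaningful on a
log scale (on TPM, virtually every expressed gene passes), so the pipeline
log-transforms linear input before filtering and modeling; this is
configurable. Sample variance uses ddof = 1. Also unsupervised, applied
once.

(c) **Supervised selection** — genes are ranked by their one-way ANOVA
*F*-score against the binary response (for two groups, *F* equals the
squared pooled-variance *t*); the top *m* are kept and standardized to zero
mean, unit variance (ddof = 0; a zero spread is replaced by 1 so constant
features map to 0 rather than NaN). *F* is computed on raw (unstandardized)
features — the ranking is identical either way for two groups. Ties in *F*
break lexicographically by gene id so the ranking is deterministic.

(d) **Ensemble classification** — an unweighted average of the predicted
response probabilities of four learners: L2 logistic regression (liblinear),
random forest, RBF-kernel SVM with internal-CV Platt calibration, and
XGBoost. Averaging iterates learners in sorted-name order, making the
ensemble bit-for-bit invariant to how the learner set is written.

### Cross-validation and selection

Training runs stratified 3-fold CV repeated 5 times (repeat *r* seeds its
fold split and learners with `seed + r`). Within each training fold, the
ANOVA ranking and the scaler are refit from scratch, and *m* together with
each learner's hyperparameters are chosen by a **nested** inner stratified
CV (up to 3 folds, reduced if a class is too small): each learner's
candidates are scored by mean inner-fold AUC (ties → first candidate); *m*
is then chosen by the mean inner-fold AUC of the ensemble of per-learner
winners (ties → smallest *m*, preferring the more parsimonious model). The
winning configuration is refit on the full training fold and applied to the
held-out fold. Selecting *m* on the same out-of-fold scores that are
reported was tried first and rejected: it inflated null AUCs to ≈ 0.69,
whereas the nested scheme keeps label-permuted and signal-free cohorts
inside [0.35, 0.65] — the property the no-leakage design exists to
guarantee.

The five repeats' out-of-fold score vectors are averaged and min–max
rescaled to [0, 1] across samples (a constant vector maps to 0.5). The
rescale bounds, the per-fold models and a PR-optimal decision threshold are
frozen into the fitted predictor.

### Hyperparameter grids and compute profiles

The default grids are deliberately small, published-default values:
logistic C ∈ {0.01, 0.1, 1, 10}; random forest 200/500 trees × depth
{∞, 5}; SVM C ∈ {0.1, 1, 10} with γ = scale; XGBoost depth {2, 3} ×
learning rate {0.05, 0.1}, 200 rounds. `PipelineConfig.fast()` is a
screening profile used throughout the test suite and examples: *m* grid
{2, 4, 8, 15, 25}, 3 repeats, one 30-tree forest, one boosting
configuration, two logistic penalties and one SVM penalty. It trades grid
resolution for a ~20× reduction in fits while keeping the filters, fold
structure, nested selection and ensemble identical; at the planted effect
sizes the two profiles recover the same structure. `for_cci()` and
`for_sc()` adapt the grid for binary interaction features (variance cutoff
0.08, random forest only, *m* up to "all") and single-cell-harmonized
cohorts (*m* up to "all"), respectively.

### Prediction on new samples

Fold models are persisted, and scoring routes each sample through the
models that did not train on it: a sample that was part of training
receives exactly its out-of-fold prediction (so re-predicting the training
cohort reproduces the stored fitted scores to the last bit), while unseen
samples are scored by all fold models and averaged. Selected genes missing
from a new cohort are imputed at their training-fold means — i.e. at a
standardized value of 0, a neutral contribution — and the imputation count
is logged; scoring fails only if every selected gene is absent. New score
vectors are rescaled across the new samples, which preserves ranking-based
metrics while absorbing cohort-level location/scale shifts.

### Baselines and variants

The **bulk baseline** is the identical pipeline with stage (a) skipped
(no confidence scores exist for bulk). The **fraction baseline** uses the
cell-type abundance vector as the complete feature set: stages (a) and (c)
are skipped, and the variance filter is bypassed as well, because fractions
live in [0, 1] where a 0.1 variance cut would delete essentially every
feature and contradict "all fractions used". The **multi-cell ensemble**
prefilters each cell type by its own confidence column, namespaces gene ids
as `celltype::gene`, concatenates, and proceeds with stages (b)–(d); with a
reference set of *n* prominent cell types the exhaustive 2–3-way catalog
has C(n,2) + C(n,3) models (56 for n = 7, 20 for n = 5).

**Single-cell harmonization** aligns scRNA-seq with deconvolution-style
output: per cell type, the top 3,500 highly variable genes (variance of
log1p expression across cells, ties lexicographic) are kept and each
patient's expression is the mean over their cells of that type; confidence
is 1 everywhere and fractions follow cell counts. Patients without cells of
a type are simply absent from that type's matrix. The **pseudobulk mixture
baseline** is the per-patient mean over all cells regardless of type.

## The interaction arm

A candidate CCI is one (ligand cell type, ligand gene, receptor cell type,
receptor gene) quadruplet per ligand–receptor pair and ordered cell-type
pair: |pairs|·k·(k−1) without autocrine (same-cell-type) quadruplets,
|pairs|·k² with them. Autocrine quadruplets are included when curating a
full database (the plausible-interaction catalog has no reason to exclude
self-signaling) and excluded in the three-cell-type single-cell validation
setting, where the cross-type channels are the object of study; both are
exposed as a flag.

**Curation.** Cells are pooled across patients. The observed score of a
quadruplet is the product of the two cell-type mean expressions — chosen
for symmetry and positivity; the product form means a quadruplet scores
high only when *both* sides are elevated in their compartments. The null
redistributes cell-type labels over the pooled cells (B = 100 permutations
by default, configurable), and the empirical p-value is
(1 + #{null ≥ observed})/(B + 1), bounded below by 1/(B+1) and uniform
under exchangeability. The tail is switchable (`null_tail ∈ {ge, le}`) for
the mirrored reading in which depletion, not enrichment, flags an
interaction; `ge` is the default since specificity is what makes an
interaction plausible. Quadruplets touching a cell type with zero cells get
p = 1 with a warning. P ≤ 0.05 flags a quadruplet "likely".

**Activity.** In a deconvolved cohort, quadruplet *q* is active in sample
*s* iff ligand expression at *s* strictly exceeds the ligand gene's
across-sample median in the ligand cell type, and likewise on the receptor
side. Strict comparison means a constant gene can never be active (it
cannot exceed its own median), and with an even sample count and distinct
values the per-gene activation rate is exactly ½, bounding quadruplet
activity at ½. Activity defaults to the database's likely subset.

**Classification and directionality.** The binary activity matrix goes
through the pipeline with variance cutoff 0.08 (a CCI active in 1 of 100
samples has variance ≈ 0.0099 and is dropped), feature grid 2 ≤ *m* ≤ all,
and a random-forest-only "ensemble" whose mean decrease in Gini impurity —
averaged over repeats and folds, with unselected quadruplets scoring 0 —
ranks the CCIs. Each quadruplet's 2×2 (active × response) table gets a
two-sided Fisher exact test, BH adjustment across quadruplets, and a sign:
+1 if OR > 1 with adjusted p ≤ 0.05 (responder-enriched), −1 if OR < 1
likewise, else 0. The reported OR carries the Haldane–Anscombe +0.5
correction when any cell is zero; the Fisher p is computed on the
uncorrected table.

**Pseudopatient validation.** Cells are pooled per response group; each of
`reps_per_group` (default 100) pseudopatients per group draws 30% of its
group's cells per cell type without replacement (⌊frac·n⌋, at least 1).
Each pseudopatient's quadruplets get an empirical p over its own cells with
its own permutation null — a per-pseudopatient null was chosen over a
shared one so each replicate is a self-contained resample — and p ≤ 0.05
marks the CCI active. The response score is Σ activity·sign over the
queried quadruplets, min–max rescaled (constant → 0.5). Expression is
restricted to the genes appearing in the queried quadruplets before any
permutation work; this is exact, not an approximation, and is what keeps
200 pseudopatients × 100 permutations tractable.

## Deconvolution benchmark harness

Pseudobulk benchmarks are mixed from single cells: patient-wise (each
patient's own cells; the pseudobulk is exactly the fraction-weighted sum of
the per-cell-type truth means) or resampled ("pseudopatients" with
Dirichlet(1,…,1) mixing proportions, cells drawn with replacement, 500
cells each by default; truth is recorded from the realized draw so the
reconstruction identity holds exactly). Optional multiplicative lognormal
noise on the pseudobulk produces the noisy variants. Accuracy against
truth uses Kendall τ-b (tie-corrected, since TPM ties occur): per cell type
across samples for fractions, per gene × cell type across samples for
expression, with a two-sided p-value (exact enumeration for n ≤ 10 without
ties, normal approximation otherwise). Genes with τ ≥ 0.3 and p ≤ 0.05
count as accurately inferred; both cutoffs are arguments, and counts are
monotone in them by construction.

## Evaluation metrics

AUC is the Mann–Whitney statistic normalized by n₊·n₋ (ties ½); average
precision is the step sum Σ (R_k − R_{k−1})·P_k with ties grouped. The
decision threshold maximizes F1 over the midpoints between consecutive
unique training scores — midpoints rather than the scores themselves so
the returned threshold is strictly inside the score range (for rescaled
scores, strictly inside (0, 1)) and the degenerate all-positive rule is
never returned; F1 ties break toward the lowest midpoint (maximal recall),
and the threshold is learned once on the pooled averaged training scores
rather than per repeat. DOR binarizes at the threshold (positive means
score ≥ threshold) and applies the +0.5 correction to every cell whenever
any cell is zero, keeping it finite; a random predictor has geometric-mean
DOR ≈ 1. The one-tailed Wilcoxon rank-sum test (positive group
stochastically greater) uses exact enumeration for pooled n ≤ 12 without
ties and the tie-corrected normal approximation otherwise. BH adjustment is
the standard step-up with monotonicity enforcement. Survival stratification
splits at a fixed score of 0.5 (High means strictly greater), fits
Kaplan–Meier curves per group and tests with the unweighted
(Mantel–Haenszel) log-rank statistic; a group with fewer than two samples
is an error naming the threshold.

## The synthetic-data generator

The generator emulates the *structure* of a deconvolved treatment cohort,
not the full messiness of scRNA-seq. Cell-level log-expression is
μ_g + patient effect + planted shifts + ε, with gene means μ_g ~ N(1, 1),
patient effects N(0, noise_sd) drawn per (patient, cell type, gene), unit
cell-level noise, and values exponentiated (lognormal baseline). Defaults —
80 patients, responder fraction 0.5, 4 cell types, 200 genes, 30 cells per
patient per type, noise_sd = 0.5 — were fixed once at sizes typical of
neoadjuvant-response cohorts and are the conditions under which the planted
recovery guarantees are stated. Response signal is planted by shifting the
named genes by the stated effect (natural-log units) in responders within
one cell type. CCI planting shifts the ligand gene in the ligand cell type
and the receptor gene in the receptor cell type: a constitutive
cell-type-specificity term (default 2.0 log-units, so curation flags the
quadruplet as plausible) plus a response-coupled term (default 1.5) in the
enriched class, so the median activation rule fires differentially;
direction 0 plants a specificity-only decoy. The rank-based methods
downstream make the exact distributional family non-critical. A single
spec seed drives every draw; the same seed reproduces every matrix
bit for bit.

What the generator does **not** model: count noise/dropout, library-size
heterogeneity, batch effects, gene–gene correlation beyond the planted
structure, or deconvolution error (fixtures hand the per-patient cell-type
means to the pipeline directly, with a configurable confidence profile).
Passing planted-recovery tests therefore demonstrates that the machinery
recovers signal of the stated size under clean conditions — a necessary
correctness property — not that real cohorts of this size yield similar
AUCs.

One interaction between generator and method is worth knowing: the
pseudopatient permutation null assumes cells are exchangeable, but cells
from one patient share their patient effect. With many cells per
pseudopatient and sizeable patient-level noise this pseudoreplication makes
the empirical p-values anti-conservative (constitutively specific
interactions activate in every pseudopatient). The pseudopatient example
therefore plants a responder-only interaction with low patient noise; real
single-cell validations face the same caveat.

## Problem sizes used by the test suite

The suite's heavy protocols run at: planted cell-type recovery — 80
patients × 200 genes × 3 cell types × 10 seeds, effect 1.5 on 10 genes,
fast profile; end-to-end CCI recovery — 60 patients × 60 genes × 3 cell
types × 10 seeds, 1 planted + 8 decoy interactions, B = 100; pseudopatient
counts — a 5,010-cell cohort with 100 replicates per group; oracle
equivalence — 100 random fixtures per primitive; random-predictor
calibration — 1,000 replicates at n = 200. Dilution and complementarity
properties run at 60 patients with 2–3 seeds. These sizes are the package's
own test conditions; the methods scale to larger cohorts linearly in
samples and features.

## Known limitations

- The confidence and variance filters are applied cohort-wide (they are
  unsupervised); only supervised steps are fold-nested.
- Probability calibration is limited to min–max rescaling; scores are
  rankings, not calibrated probabilities.
- The leave-one-out CV variant is available only by setting
  `n_cv_folds = n − 1`; it is not a separately tuned path.
- Fisher's exact test is conservative on the small 2×2 tables typical of
  small cohorts; signed CCIs are correspondingly conservative.
- The curation score (product of means) weights highly expressed genes
  more than a fraction-expressing criterion would; the permutation null
  absorbs overall expression level but not within-cell-type outliers.
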