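"""Score deconvolution accuracy against pseudobulk ground truth.

Single cells are mixed into pseudobulk samples with known per-cell-type
expression and fractions.  A mock 'inference' (truth plus noise) is scored
with Kendall τ per cell type (fractions) and per gene × cell type
(expression); genes with τ ≥ 0.3 and P ≤ 0.05 count as accurately
inferred.
"""

import numpy as np

from tmepredict import (
    DeconvolvedCohort,
    ExpressionMatrix,
    SyntheticSpec,
    count_accurate_genes,
    generate_sc_cohort,
    kendall_accuracy,
    mix_pseudobulk,
    truth_as_cohort,
)

spec = SyntheticSpec(
    n_patients=20, n_genes=80, cell_types=("B-cells", "myeloid", "T-cells"),
    cells_per_patient_per_type=(10, 30), seed=2,
)
sc = generate_sc_cohort(spec)
bench = mix_pseudobulk(sc, mixing_mode="patientwise")

# mock inference: ground truth corrupted by multiplicative lognormal noise
rng = np.random.default_rng(2)
truth = truth_as_cohort(bench)
noisy = {
    ct: ExpressionMatrix(em.values * np.exp(rng.normal(0, 0.6, em.shape)), "tpm")
    for ct, em in truth.expression.items()
}
inferred = DeconvolvedCohort(
    cell_types=truth.cell_types, expression=noisy,
    confidence=truth.confidence, fractions=truth.fractions,
)

report = kendall_accuracy(inferred, bench)
counts = count_accurate_genes(report)  # tau >= 0.3, p <= 0.05
print(f"{'cell type':<10} {'fraction tau':>12} {'median expr tau':>16} {'accurate genes':>15}")
for ct in report.cell_types:
    print(
        f"{ct:<10} {report.fraction_tau[ct]:12.3f} "
        f"{report.expression_tau[ct].median():16.3f} {counts[ct]:15d} / 80"
    )
print(
    "\nFraction tau is 1 because fractions were left exact; expression tau "
    "drops with the injected noise, and the accurate-gene count shows how "
    "many genes a downstream analysis could trust."
)
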