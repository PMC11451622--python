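"""Discover a response-predictive cell-cell interaction from scratch.

A ligand-receptor interaction (B-cells G0001 → myeloid G0002) is planted:
both genes are cell-type-specific, and co-elevated in responders.  The
workflow (1) curates the plausible-interaction database from single cells
by permutation testing, (2) infers binary per-sample activity from the
deconvolved cohort by the median rule, (3) trains a random forest on the
activity matrix, and (4) reads off Gini importances and Fisher-test
directionality.  The planted quadruplet should rank first, signed +.
"""

from tmepredict import (
    LRPairList,
    PipelineConfig,
    PlantedCCI,
    SyntheticSpec,
    cci_directionality,
    cci_feature_importance,
    curate_cci_database,
    fit_cci_predictor,
    generate_deconvolved_fixture,
    generate_sc_cohort,
    infer_cci_activity,
)

planted = PlantedCCI("B-cells", "G0001", "myeloid", "G0002", direction=+1)
decoys = [  # cell-type-specific but response-neutral interactions
    PlantedCCI("B-cells", "G0003", "myeloid", "G0004", 0),
    PlantedCCI("myeloid", "G0005", "T-cells", "G0006", 0),
    PlantedCCI("T-cells", "G0007", "B-cells", "G0008", 0),
    PlantedCCI("myeloid", "G0009", "B-cells", "G0010", 0),
]
spec = SyntheticSpec(
    n_patients=60, n_genes=60, cell_types=("B-cells", "myeloid", "T-cells"),
    cells_per_patient_per_type=20, planted_ccis=(planted, *decoys), seed=0,
)
lr = LRPairList(tuple((c.ligand_gene, c.receptor_gene) for c in (planted, *decoys)))

sc = generate_sc_cohort(spec)
db = curate_cci_database(sc, lr, B=100, seed=0)
print(f"database: {len(db.quadruplets)} candidates, {len(db.likely)} likely (P ≤ 0.05)")

cohort, labels = generate_deconvolved_fixture(spec)
activity = infer_cci_activity(cohort, db)
print(f"activity matrix: {activity.activity.shape[0]} CCIs × {activity.activity.shape[1]} samples")

model = fit_cci_predictor(activity, labels, PipelineConfig.for_cci(fast=True, seed=0))
print(f"out-of-fold AUC: {model.oof_auc():.3f}")

importance = cci_feature_importance(model)
directions = cci_directionality(activity, labels)
print("\ntop 3 interactions by Gini importance:")
for key in importance.index[:3]:
    print(
        f"  {key:<35} importance={importance[key]:.3f} "
        f"OR={directions.loc[key, 'odds_ratio']:.2f} sign={int(directions.loc[key, 'sign']):+d}"
    )
print(
    "\nThe planted B-cells→myeloid interaction should lead with sign +1 "
    "(odds ratio > 1 = enriched in responders); decoys carry sign 0."
)
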