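"""Synthetic cohorts with planted, recoverable structure.

Three generators stand in for real deconvolved breast-tumor cohorts:

* :func:`generate_sc_cohort` — a single-cell cohort with lognormal baseline
  expression, optional response-predictive genes planted per cell type, and
  optional planted ligand-receptor interactions whose genes are both
  cell-type-specific and (for directed plantings) co-elevated in one
  response class.
* :func:`mix_pseudobulk` — pseudobulk benchmark cohorts mixed from single
  cells with exact ground-truth fractions and per-cell-type expression,
  patient-wise or as resampled "pseudopatient" mixtures, optionally with
  multiplicative lognormal noise.
* :func:`generate_deconvolved_fixture` — a deconvolved cohort (per-cell-type
  patient expression + confidence + fractions) with known labels, emulating
  deconvolution output downstream tools consume.

All randomness flows from a single spec seed; derived generators use child
seeds, so a fixed seed reproduces every matrix bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import (
    DeconvolvedCohort,
    ExpressionMatrix,
    ResponseLabels,
    SingleCellCohort,
)

__all__ = [
    "PlantedCCI",
    "SyntheticSpec",
    "BenchmarkCohort",
    "generate_sc_cohort",
    "mix_pseudobulk",
    "generate_deconvolved_fixture",
]

DEFAULT_CELL_TYPES = ("B-cells", "myeloid", "T-cells", "malignant")


@dataclass(frozen=True)
class PlantedCCI:
    """A planted ligand-receptor interaction between two cell types.

    ``direction`` +1 co-elevates ligand and receptor in responders,
    −1 in non-responders, 0 plants cell-type specificity only (a decoy
    interaction that is plausible but carries no response signal).
    """

    ligand_celltype: str
    ligand_gene: str
    receptor_celltype: str
    receptor_gene: str
    direction: int = 1


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic cohort.

    Effect sizes are in natural-log units of cell-level expression.
    ``cells_per_patient_per_type`` may be an int, an inclusive (lo, hi)
    range, or a per-cell-type mapping.
    """

    n_patients: int = 80
    responder_fraction: float = 0.5
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES
    n_genes: int = 200
    cells_per_patient_per_type: int | tuple[int, int] | Mapping[str, int] = 30
    signal_genes: Mapping[str, tuple[Sequence[str], float]] = field(default_factory=dict)
    planted_ccis: Sequence[PlantedCCI] = ()
    noise_sd: float = 0.5
    cci_specificity: float = 2.0
    cci_effect: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cell_types) == 0:
            raise ValueError("cell-type list must be non-empty")
        if not 0 < self.responder_fraction < 1:
            raise ValueError("responder_fraction must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        universe = set(self.gene_ids)
        for ct, (genes, effect) in self.signal_genes.items():
            if ct not in self.cell_types:
                raise ValueError(f"signal cell type {ct!r} not in cohort cell types")
            if not set(genes) <= universe:
                raise ValueError(f"signal genes for {ct!r} outside the gene universe")
            if not np.isfinite(effect):
                raise ValueError("effect sizes must be finite")
        for cci in self.planted_ccis:
            for g in (cci.ligand_gene, cci.receptor_gene):
                if g not in universe:
                    raise ValueError(f"planted CCI gene {g!r} outside the gene universe")
            for ct in (cci.ligand_celltype, cci.receptor_celltype):
                if ct not in self.cell_types:
                    raise ValueError(f"planted CCI cell type {ct!r} not in cohort")

    @property
    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    @property
    def patient_ids(self) -> list[str]:
        width = max(3, len(str(self.n_patients)))
        return [f"P{i + 1:0{width}d}" for i in range(self.n_patients)]

    def n_cells(self, cell_type: str, rng: np.random.Generator) -> int:
        spec = self.cells_per_patient_per_type
        if isinstance(spec, Mapping):
            return int(spec[cell_type])
        if isinstance(spec, tuple):
            lo, hi = spec
            return int(rng.integers(lo, hi + 1))
        return int(spec)


@dataclass
class BenchmarkCohort:
    """A pseudobulk cohort with exact deconvolution ground truth."""

    pseudobulk: ExpressionMatrix
    truth_fractions: pd.DataFrame
    truth_expression: dict[str, ExpressionMatrix]
    noise_level_tag: str


def _assign_responders(spec: SyntheticSpec, rng: np.random.Generator) -> pd.Series:
    n_resp = int(round(spec.n_patients * spec.responder_fraction))
    order = rng.permutation(spec.n_patients)
    labels = np.zeros(spec.n_patients, dtype=np.int8)
    labels[order[:n_resp]] = 1
    return pd.Series(labels, index=spec.patient_ids)


def generate_sc_cohort(spec: SyntheticSpec) -> SingleCellCohort:
    """Draw a synthetic single-cell cohort under ``spec``.

    Cell-level log-expression is mu_g + patient effect (sd = ``noise_sd``)
    + planted shifts + unit-variance cell noise; values are exponentiated,
    giving a lognormal baseline. Response-predictive genes are shifted by
    the stated effect in responder patients within their designated cell
    type; planted CCI genes gain cell-type specificity everywhere and a
    response-coupled co-elevation in the enriched class.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    ct_list = list(spec.cell_types)
    mu = rng.normal(1.0, 1.0, size=spec.n_genes)
    labels = _assign_responders(spec, rng)

    # per-cell-type shift applied to every patient (specificity) and to one
    # response class only (signal)
    base_shift = {ct: np.zeros(spec.n_genes) for ct in ct_list}
    class_shift = {(ct, cls): np.zeros(spec.n_genes) for ct in ct_list for cls in (0, 1)}
    for ct, (sig_genes, effect) in spec.signal_genes.items():
        for g in sig_genes:
            class_shift[(ct, 1)][gene_pos[g]] += float(effect)
    for cci in spec.planted_ccis:
        for ct, g in (
            (cci.ligand_celltype, cci.ligand_gene),
            (cci.receptor_celltype, cci.receptor_gene),
        ):
            base_shift[ct][gene_pos[g]] += spec.cci_specificity
            if cci.direction > 0:
                class_shift[(ct, 1)][gene_pos[g]] += spec.cci_effect
            elif cci.direction < 0:
                class_shift[(ct, 0)][gene_pos[g]] += spec.cci_effect

    blocks, cell_ids, cell_patients, cell_types = [], [], [], []
    for patient in spec.patient_ids:
        cls = int(labels[patient])
        for ct in ct_list:
            n_cells = spec.n_cells(ct, rng)
            patient_effect = rng.normal(0.0, spec.noise_sd, size=spec.n_genes)
            loc = mu + base_shift[ct] + class_shift[(ct, cls)] + patient_effect
            log_expr = loc[None, :] + rng.normal(0.0, 1.0, size=(n_cells, spec.n_genes))
            blocks.append(np.exp(log_expr))
            ct_token = ct.replace(" ", "_")
            cell_ids.extend(f"{patient}_{ct_token}_C{i + 1:04d}" for i in range(n_cells))
            cell_patients.extend([patient] * n_cells)
            cell_types.extend([ct] * n_cells)

    expr = pd.DataFrame(np.vstack(blocks), index=cell_ids, columns=genes)
    return SingleCellCohort(
        expression=expr,
        patient_ids=pd.Series(cell_patients, index=cell_ids),
        cell_types=pd.Series(cell_types, index=cell_ids),
        patient_labels=ResponseLabels(labels),
    )


def mix_pseudobulk(
    sc: SingleCellCohort,
    n_pseudo: int = 100,
    mixing_mode: str = "patientwise",
    noise_sd: float = 0.0,
    seed: int = 0,
    cells_per_pseudo: int = 500,
) -> BenchmarkCohort:
    """Mix single cells into a pseudobulk benchmark cohort.

    ``patientwise`` sums each patient's own cells (the per-patient
    benchmark); ``resampled`` draws ``n_pseudo`` random cell mixtures with
    Dirichlet(1, ..., 1) cell-type proportions ("pseudopatients").  In both
    modes the recorded truth satisfies, before noise,
    pseudobulk(g, s) = Σ_t fraction(s, t) · truth_expression_t(g, s).
    ``noise_sd`` > 0 multiplies the pseudobulk by lognormal noise.
    """
    if n_pseudo < 1:
        raise ValueError("n_pseudo must be ≥ 1")
    if mixing_mode not in ("patientwise", "resampled"):
        raise ValueError(f"unknown mixing_mode {mixing_mode!r}")
    rng = np.random.default_rng(seed)
    genes = sc.gene_ids
    cts = sc.cell_type_set
    X = sc.expression.to_numpy()

    if mixing_mode == "patientwise":
        sample_ids = sc.patients
        cell_sets = {
            (p, t): np.flatnonzero((sc.patient_ids == p) & (sc.cell_types == t)).tolist()
            for p in sample_ids
            for t in cts
        }
        for p in sample_ids:
            if all(len(cell_sets[(p, t)]) == 0 for t in cts):
                raise ValueError(f"patient {p} has no cells")
    else:
        sample_ids = [f"PP{i + 1:04d}" for i in range(n_pseudo)]
        pools = {t: np.flatnonzero(sc.cell_types == t) for t in cts}
        empty = [t for t, pool in pools.items() if len(pool) == 0]
        if empty:
            raise ValueError(f"cell type(s) with no cells: {empty}")
        cell_sets = {}
        for s in sample_ids:
            props = rng.dirichlet(np.ones(len(cts)))
            counts = rng.multinomial(cells_per_pseudo, props)
            for t, n in zip(cts, counts):
                cell_sets[(s, t)] = (
                    rng.choice(pools[t], size=n, replace=True).tolist() if n else []
                )

    frac = pd.DataFrame(0.0, index=sample_ids, columns=cts)
    truth = {t: pd.DataFrame(0.0, index=genes, columns=sample_ids) for t in cts}
    bulk = pd.DataFrame(0.0, index=genes, columns=sample_ids)
    for s in sample_ids:
        total = sum(len(cell_sets[(s, t)]) for t in cts)
        for t in cts:
            idx = cell_sets[(s, t)]
            if not idx:
                continue
            frac.loc[s, t] = len(idx) / total
            truth[t][s] = X[idx].mean(axis=0)
        bulk[s] = sum(frac.loc[s, t] * truth[t][s] for t in cts)

    if noise_sd > 0:
        bulk = bulk * np.exp(rng.normal(0.0, noise_sd, size=bulk.shape))
        tag = f"lognormal_sd={noise_sd:g}"
    else:
        tag = "noiseless"
    return BenchmarkCohort(
        pseudobulk=ExpressionMatrix(bulk, "tpm"),
        truth_fractions=frac,
        truth_expression={t: ExpressionMatrix(truth[t], "tpm") for t in cts},
        noise_level_tag=tag,
    )


def generate_deconvolved_fixture(
    spec: SyntheticSpec,
    confidence_profile: Mapping[str, float] | None = None,
) -> tuple[DeconvolvedCohort, ResponseLabels]:
    """Deconvolved-cohort stand-in with known labels.

    Per-cell-type patient expression is the mean over that patient's cells
    of the type; the confidence matrix is 1.0 everywhere except for genes
    named in ``confidence_profile`` (gene id → confidence), which lets
    tests exercise the confidence prefilter; fractions follow cell counts.
    """
    sc = generate_sc_cohort(spec)
    genes = sc.gene_ids
    cts = list(spec.cell_types)
    patients = spec.patient_ids

    expression = {}
    counts = pd.DataFrame(0.0, index=patients, columns=cts)
    for t in cts:
        mat = pd.DataFrame(0.0, index=genes, columns=patients)
        for p in patients:
            mask = (sc.patient_ids == p) & (sc.cell_types == t)
            counts.loc[p, t] = int(mask.sum())
            if mask.any():
                mat[p] = sc.expression.loc[mask.to_numpy()].mean(axis=0).to_numpy()
        expression[t] = ExpressionMatrix(mat, "tpm")

    confidence = pd.DataFrame(1.0, index=genes, columns=cts)
    if confidence_profile:
        for g, c in confidence_profile.items():
            confidence.loc[g, :] = float(c)
    fractions = counts.div(counts.sum(axis=1), axis=0)
    cohort = DeconvolvedCohort(
        cell_types=cts,
        expression=expression,
        confidence=confidence,
        fractions=fractions,
    )
    return cohort, sc.patient_labels
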