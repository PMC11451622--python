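"""Cell-cell interaction (CCI) inference and CCI-based response prediction.

A CCI is a quadruplet (ligand cell type, ligand gene, receptor cell type,
receptor gene).  The module covers the full interaction arm of the
framework:

* curating a database of *plausible* quadruplets from single-cell data via
  empirical permutation p-values on cell-type-specific expression,
* inferring binary per-sample CCI activity from deconvolved expression
  (active when both ligand and receptor exceed their cell-type-specific
  across-sample medians),
* classifying response from the binary activity matrix with a random
  forest and extracting Gini feature importances,
* signing CCIs by responder enrichment (two-sided Fisher test with BH
  adjustment), and
* validating top CCIs in single-cell data via downsampled "pseudopatients"
  scored by their signed sum of active CCIs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import DeconvolvedCohort, LRPairList, ResponseLabels, SingleCellCohort
from .metrics import benjamini_hochberg, minmax_rescale
from .pipeline import EmptyFeatureError, FittedPredictor, PipelineConfig, fit_feature_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "CCIQuadruplet",
    "CCIDatabase",
    "CCIActivityMatrix",
    "PseudoPatientSet",
    "enumerate_candidate_ccis",
    "curate_cci_database",
    "infer_cci_activity",
    "fit_cci_predictor",
    "cci_feature_importance",
    "cci_directionality",
    "generate_pseudopatients",
    "signed_cci_score",
]


class CCIQuadruplet(NamedTuple):
    ligand_celltype: str
    ligand_gene: str
    receptor_celltype: str
    receptor_gene: str

    @property
    def key(self) -> str:
        return (
            f"{self.ligand_celltype}-{self.receptor_celltype}"
            f"::{self.ligand_gene}-{self.receptor_gene}"
        )


def enumerate_candidate_ccis(
    lr: LRPairList | Sequence[tuple[str, str]],
    cell_types: Sequence[str],
    include_self: bool = False,
) -> list[CCIQuadruplet]:
    """All (pair, ordered cell-type pair) quadruplets.

    With k cell types and autocrine (same-cell-type) pairs excluded the
    count is |lr|·k·(k−1); including them it is |lr|·k².
    """
    out = []
    for lg, rg in lr:
        for lct in cell_types:
            for rct in cell_types:
                if not include_self and lct == rct:
                    continue
                out.append(CCIQuadruplet(lct, lg, rct, rg))
    return out


@dataclass
class CCIDatabase:
    """Plausible quadruplets with empirical permutation p-values.

    ``table`` is indexed by quadruplet key with the four component columns
    plus ``empirical_p`` and ``likely`` (p ≤ alpha).
    """

    table: pd.DataFrame
    alpha: float
    n_permutations: int

    @property
    def quadruplets(self) -> list[CCIQuadruplet]:
        return [
            CCIQuadruplet(r.ligand_celltype, r.ligand_gene, r.receptor_celltype, r.receptor_gene)
            for r in self.table.itertuples()
        ]

    @property
    def likely(self) -> list[CCIQuadruplet]:
        sub = self.table[self.table["likely"]]
        return [
            CCIQuadruplet(r.ligand_celltype, r.ligand_gene, r.receptor_celltype, r.receptor_gene)
            for r in sub.itertuples()
        ]


def _group_means(
    X: np.ndarray, labels: np.ndarray, cts: list[str]
) -> np.ndarray:
    """Mean expression per cell type: returns (k, genes); NaN for empty types."""
    k, g = len(cts), X.shape[1]
    means = np.full((k, g), np.nan)
    for i, t in enumerate(cts):
        mask = labels == t
        if mask.any():
            means[i] = X[mask].mean(axis=0)
    return means


def _empirical_cci_pvalues(
    X: np.ndarray,
    labels: np.ndarray,
    cts: list[str],
    lct_i: np.ndarray,
    lg_i: np.ndarray,
    rct_i: np.ndarray,
    rg_i: np.ndarray,
    B: int,
    rng: np.random.Generator,
    null_tail: str = "ge",
) -> np.ndarray:
    """Permutation p-values for quadruplet scores.

    The observed score of a quadruplet is (mean ligand expression in the
    ligand cell type) × (mean receptor expression in the receptor cell
    type); the null redistributes cell-type labels over the pooled cells.
    p = (1 + #{null ≥ observed}) / (B + 1) for ``null_tail='ge'`` (large
    observed scores are significant), or with ≤ for the mirrored reading.
    """
    obs_means = _group_means(X, labels, cts)
    obs = obs_means[lct_i, lg_i] * obs_means[rct_i, rg_i]
    count = np.zeros(len(obs))
    valid = ~np.isnan(obs)
    for _ in range(B):
        perm = rng.permutation(X.shape[0])
        null_means = _group_means(X[perm], labels, cts)
        null = null_means[lct_i, lg_i] * null_means[rct_i, rg_i]
        if null_tail == "ge":
            count[valid] += null[valid] >= obs[valid]
        else:
            count[valid] += null[valid] <= obs[valid]
    p = (1.0 + count) / (B + 1.0)
    p[~valid] = 1.0
    return p


def curate_cci_database(
    sc: SingleCellCohort,
    lr: LRPairList,
    B: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    include_self: bool = True,
    cell_types: Sequence[str] | None = None,
    null_tail: str = "ge",
) -> CCIDatabase:
    """Build the plausible-CCI database from pooled single cells.

    Quadruplets whose ligand or receptor gene is absent from the cohort are
    dropped (logged); quadruplets involving a cell type with no cells get
    p = 1 with a warning.  A quadruplet with empirical p ≤ ``alpha`` is
    flagged 'likely' to occur.
    """
    cts = list(cell_types) if cell_types is not None else sc.cell_type_set
    genes = set(sc.gene_ids)
    quads = enumerate_candidate_ccis(lr, cts, include_self=include_self)
    kept = [q for q in quads if q.ligand_gene in genes and q.receptor_gene in genes]
    if len(kept) < len(quads):
        logger.info("dropped %d quadruplet(s) with absent genes", len(quads) - len(kept))
    if not kept:
        raise ValueError("no quadruplet has both genes in the cohort")

    needed = sorted({g for q in kept for g in (q.ligand_gene, q.receptor_gene)})
    gene_pos = {g: i for i, g in enumerate(needed)}
    ct_pos = {t: i for i, t in enumerate(cts)}
    X = sc.expression[needed].to_numpy()
    labels = sc.cell_types.to_numpy()
    empty = [t for t in cts if not (labels == t).any()]
    if empty:
        logger.warning("cell type(s) with no cells get p = 1: %s", empty)

    lct_i = np.array([ct_pos[q.ligand_celltype] for q in kept])
    lg_i = np.array([gene_pos[q.ligand_gene] for q in kept])
    rct_i = np.array([ct_pos[q.receptor_celltype] for q in kept])
    rg_i = np.array([gene_pos[q.receptor_gene] for q in kept])
    rng = np.random.default_rng(seed)
    p = _empirical_cci_pvalues(X, labels, cts, lct_i, lg_i, rct_i, rg_i, B, rng, null_tail)

    table = pd.DataFrame(
        {
            "ligand_celltype": [q.ligand_celltype for q in kept],
            "ligand_gene": [q.ligand_gene for q in kept],
            "receptor_celltype": [q.receptor_celltype for q in kept],
            "receptor_gene": [q.receptor_gene for q in kept],
            "empirical_p": p,
            "likely": p <= alpha,
        },
        index=[q.key for q in kept],
    )
    return CCIDatabase(table=table, alpha=alpha, n_permutations=B)


@dataclass
class CCIActivityMatrix:
    """Binary quadruplets × samples activity matrix."""

    activity: pd.DataFrame
    quadruplets: list[CCIQuadruplet]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.activity.columns)


def infer_cci_activity(
    cohort: DeconvolvedCohort,
    db: CCIDatabase | Sequence[CCIQuadruplet],
    likely_only: bool = True,
) -> CCIActivityMatrix:
    """Median-rule activity: a quadruplet is active in a sample iff both
    ligand and receptor expression strictly exceed their cell-type-specific
    across-sample medians.

    Quadruplets whose genes or cell types are absent from the cohort are
    dropped with a logged count.
    """
    if isinstance(db, CCIDatabase):
        quads = db.likely if likely_only else db.quadruplets
    else:
        quads = list(db)
    samples = cohort.sample_ids

    above: dict[str, pd.DataFrame] = {}
    for ct in cohort.cell_types:
        vals = cohort.expression[ct].values
        med = vals.median(axis=1)
        above[ct] = vals.gt(med, axis=0)

    kept, rows = [], []
    for q in quads:
        if q.ligand_celltype not in above or q.receptor_celltype not in above:
            continue
        lig = above[q.ligand_celltype]
        rec = above[q.receptor_celltype]
        if q.ligand_gene not in lig.index or q.receptor_gene not in rec.index:
            continue
        kept.append(q)
        rows.append(
            (lig.loc[q.ligand_gene, samples] & rec.loc[q.receptor_gene, samples]).to_numpy()
        )
    if len(kept) < len(quads):
        logger.info("dropped %d quadruplet(s) absent from the cohort", len(quads) - len(kept))
    if not kept:
        raise ValueError("no database quadruplet is representable in the cohort")
    activity = pd.DataFrame(
        np.vstack(rows).astype(np.int8), index=[q.key for q in kept], columns=samples
    )
    return CCIActivityMatrix(activity=activity, quadruplets=kept)


def fit_cci_predictor(
    activity: CCIActivityMatrix,
    y: ResponseLabels,
    config: PipelineConfig | None = None,
) -> FittedPredictor:
    """Random-forest response predictor on binary CCI activity.

    Confidence prefiltering does not apply; the low-variance cut-off drops
    to 0.08 and feature selection runs over 2 ≤ m ≤ 'all'.
    """
    config = config or PipelineConfig.for_cci()
    X = activity.activity.T.astype(float)
    var = X.var(axis=0, ddof=1)
    keep = list(var.index[var >= config.variance_min])
    if not keep:
        raise EmptyFeatureError(f"no CCI passes variance ≥ {config.variance_min}")
    return fit_feature_matrix(
        X[keep], y, config, select_features=True, mode="cci", log_transform=False
    )


def cci_feature_importance(model: FittedPredictor) -> pd.Series:
    """Mean decrease in Gini impurity per quadruplet, averaged over
    repeats and folds; unselected quadruplets score 0.  Descending order
    defines the top CCIs."""
    if set(model.config.learner_set) != {"random_forest"}:
        raise ValueError("feature importances require a random-forest-only model")
    imp = pd.Series(0.0, index=model.feature_space)
    n = 0
    for rep in model.repeats:
        for fm in rep.fold_models:
            rf = fm.models["random_forest"]
            imp[fm.features] = imp[fm.features] + rf.feature_importances_
            n += 1
    imp /= n
    order = sorted(imp.index, key=lambda k: (-imp[k], k))
    return imp.loc[order]


def cci_directionality(
    activity: CCIActivityMatrix,
    y: ResponseLabels,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Sign each quadruplet by responder enrichment.

    For each quadruplet a 2×2 (active/inactive × responder/non-responder)
    table is tested with a two-sided Fisher exact test; p-values are BH
    adjusted across quadruplets.  Sign is +1 for OR > 1 with adjusted
    p ≤ ``fdr_alpha`` (enriched in responders), −1 for OR < 1 likewise,
    else 0.  The reported OR carries the Haldane-Anscombe +0.5 correction
    when any cell is zero; the Fisher p uses the uncorrected table.
    """
    labels = y.align_to(activity.sample_ids).labels
    ResponseLabels(labels).require_both_classes()
    A = activity.activity[labels.index].to_numpy()
    yv = labels.to_numpy()
    n_r = int((yv == 1).sum())
    n_nr = int((yv == 0).sum())

    rows = []
    for i in range(A.shape[0]):
        a = int(A[i][yv == 1].sum())        # active in responders
        b = int(A[i][yv == 0].sum())        # active in non-responders
        c, d = n_r - a, n_nr - b
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * d) / (b * c)
        rows.append((orr, p))
    orr = np.array([r[0] for r in rows])
    praw = np.array([r[1] for r in rows])
    padj = benjamini_hochberg(praw)
    sign = np.zeros(len(rows), dtype=int)
    sign[(orr > 1) & (padj <= fdr_alpha)] = 1
    sign[(orr < 1) & (padj <= fdr_alpha)] = -1

    out = pd.DataFrame(
        {
            "odds_ratio": orr,
            "fisher_p": praw,
            "fdr_adjusted_p": padj,
            "sign": sign,
        },
        index=activity.activity.index,
    )
    for col in ("ligand_celltype", "ligand_gene", "receptor_celltype", "receptor_gene"):
        out[col] = [getattr(q, col) for q in activity.quadruplets]
    return out


@dataclass
class PseudoPatientSet:
    """Downsampled single-cell 'pseudopatients' with per-CCI activity.

    ``groups`` maps each pseudopatient to its response group; ``pvalues``
    and ``activity`` are quadruplets × pseudopatients; ``cell_subsets``
    records the constituent cell ids per pseudopatient.
    """

    groups: pd.Series
    pvalues: pd.DataFrame
    activity: pd.DataFrame
    cell_subsets: dict[str, list[str]]
    quadruplets: list[CCIQuadruplet]

    def __len__(self) -> int:
        return len(self.groups)


def generate_pseudopatients(
    sc: SingleCellCohort,
    y_patient: ResponseLabels,
    db_subset: Sequence[CCIQuadruplet],
    frac: float = 0.3,
    reps_per_group: int = 100,
    alpha: float = 0.05,
    B: int = 100,
    seed: int = 0,
    null_tail: str = "ge",
) -> PseudoPatientSet:
    """Pool cells per response group and downsample replicates.

    For each group, ``reps_per_group`` pseudopatients are drawn, each
    holding ``frac`` of that group's cells per cell type (without
    replacement within a draw).  Each pseudopatient's quadruplets get an
    empirical permutation p-value over its own cells, and a CCI is
    'active' when p ≤ ``alpha``.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must lie in (0, 1]")
    labels = y_patient.labels
    member = sc.patient_ids.map(labels)
    if member.isna().any():
        raise ValueError("every cell's patient needs a response label")
    if labels.nunique() < 2:
        raise ValueError("two response groups are required")

    cts = sc.cell_type_set
    genes = set(sc.gene_ids)
    kept = [q for q in db_subset if q.ligand_gene in genes and q.receptor_gene in genes]
    if len(kept) < len(db_subset):
        logger.info("dropped %d quadruplet(s) with absent genes", len(db_subset) - len(kept))
    if not kept:
        raise ValueError("no quadruplet has both genes in the single-cell data")
    needed = sorted({g for q in kept for g in (q.ligand_gene, q.receptor_gene)})
    gene_pos = {g: i for i, g in enumerate(needed)}
    ct_pos = {t: i for i, t in enumerate(cts)}
    lct_i = np.array([ct_pos[q.ligand_celltype] for q in kept])
    lg_i = np.array([gene_pos[q.ligand_gene] for q in kept])
    rct_i = np.array([ct_pos[q.receptor_celltype] for q in kept])
    rg_i = np.array([gene_pos[q.receptor_gene] for q in kept])

    Xall = sc.expression[needed].to_numpy()
    ctall = sc.cell_types.to_numpy()
    cell_ids = np.array(sc.cell_ids)
    min_cells = ceil(1.0 / frac)
    pools: dict[tuple[int, str], np.ndarray] = {}
    for grp in (1, 0):
        for t in cts:
            pool = np.flatnonzero((member == grp).to_numpy() & (ctall == t))
            if len(pool) < min_cells:
                raise ValueError(
                    f"group {grp} has {len(pool)} cell(s) of type {t!r}; "
                    f"need ≥ {min_cells} for frac={frac}"
                )
            pools[(grp, t)] = pool

    rng = np.random.default_rng(seed)
    ids, groups, subsets, pcols = [], [], {}, []
    for grp, tag in ((1, "R"), (0, "NR")):
        for i in range(reps_per_group):
            idx_parts = []
            for t in cts:
                pool = pools[(grp, t)]
                k = max(1, int(np.floor(frac * len(pool))))
                idx_parts.append(rng.choice(pool, size=k, replace=False))
            idx = np.concatenate(idx_parts)
            pid = f"{tag}{i + 1:03d}"
            ids.append(pid)
            groups.append(tag)
            subsets[pid] = cell_ids[idx].tolist()
            pcols.append(
                _empirical_cci_pvalues(
                    Xall[idx], ctall[idx], cts,
                    lct_i, lg_i, rct_i, rg_i, B, rng, null_tail,
                )
            )

    keys = [q.key for q in kept]
    if ids:
        pvalues = pd.DataFrame(np.column_stack(pcols), index=keys, columns=ids)
    else:
        pvalues = pd.DataFrame(index=keys, columns=ids, dtype=float)
    activity = (pvalues <= alpha).astype(np.int8)
    return PseudoPatientSet(
        groups=pd.Series(groups, index=ids, name="group"),
        pvalues=pvalues,
        activity=activity,
        cell_subsets=subsets,
        quadruplets=kept,
    )


def signed_cci_score(pp: PseudoPatientSet, directions: pd.DataFrame) -> pd.Series:
    """Signed sum of active CCIs per pseudopatient, rescaled to [0, 1].

    score(p) = Σ_q activity(q, p) · sign(q); a constant vector maps to 0.5.
    ``directions`` must cover every quadruplet of the set (as produced by
    :func:`cci_directionality`).
    """
    missing = [k for k in pp.activity.index if k not in directions.index]
    if missing:
        raise ValueError(f"directionality table missing quadruplet(s): {missing[:5]}")
    signs = directions.loc[pp.activity.index, "sign"].astype(float)
    raw = pp.activity.mul(signs, axis=0).sum(axis=0)
    return pd.Series(minmax_rescale(raw.to_numpy()), index=pp.activity.columns, name="score")
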