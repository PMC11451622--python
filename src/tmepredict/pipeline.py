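"""Four-stage ML pipeline for cell-type-specific response prediction.

Given deconvolved per-cell-type expression, each predictor applies:

(a) unsupervised prefiltering to genes deconvolved with confidence ≥ 0.99,
(b) low-variance filtering (variance ≥ 0.1 on the log2(TPM+1) scale),
(c) supervised selection of the top *m* genes by ANOVA F-score
    (2 ≤ m ≤ 25 by default), with per-gene standardization, and
(d) an unweighted ensemble of four classifiers — L2 logistic regression,
    random forest, RBF-kernel SVM and gradient-boosted trees — whose mean
    probability is the response score.

Training uses stratified three-fold cross-validation repeated five times
with distinct splits: feature ranking and standardization are refit inside
each training fold, hyperparameters and *m* are picked per repeat on
out-of-fold AUC, the five out-of-fold score vectors are averaged and the
result min-max rescaled to [0, 1].  Variants cover bulk expression (stage
(a) skipped), cell fractions (stages (a)-(c) skipped), concatenated
multi-cell-type ensembles, and single-cell-harmonized cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .data import DeconvolvedCohort, ExpressionMatrix, ResponseLabels, SingleCellCohort
from .metrics import minmax_rescale, optimal_threshold_from_pr, roc_auc

logger = logging.getLogger(__name__)

# internal-CV Platt scaling is the intended calibration here; silence the
# sklearn 1.9 deprecation chatter it triggers on every fit
warnings.filterwarnings(
    "ignore", message="The `probability` parameter", category=FutureWarning
)

__all__ = [
    "EmptyFeatureError",
    "PipelineConfig",
    "FittedPredictor",
    "confidence_prefilter",
    "variance_filter",
    "rank_features_anova",
    "fit_feature_matrix",
    "fit_celltype_predictor",
    "fit_multicell_predictor",
    "fit_bulk_baseline",
    "fit_fraction_baseline",
    "predict_scores",
    "harmonize_sc_expression",
    "pseudobulk_mixture_baseline",
    "multicell_combinations",
]

LEARNERS = ("logistic", "random_forest", "svm", "xgboost")

DEFAULT_GRIDS: dict[str, list[dict]] = {
    "logistic": [{"C": c} for c in (0.01, 0.1, 1.0, 10.0)],
    "random_forest": [
        {"n_estimators": n, "max_depth": d} for n in (200, 500) for d in (None, 5)
    ],
    "svm": [{"C": c} for c in (0.1, 1.0, 10.0)],
    "xgboost": [
        {"max_depth": d, "learning_rate": lr, "n_estimators": 200}
        for d in (2, 3)
        for lr in (0.05, 0.1)
    ],
}

FAST_GRIDS: dict[str, list[dict]] = {
    "logistic": [{"C": c} for c in (0.01, 1.0)],
    "random_forest": [{"n_estimators": 30, "max_depth": None}],
    "svm": [{"C": 1.0}],
    "xgboost": [{"max_depth": 2, "learning_rate": 0.1, "n_estimators": 100}],
}


class EmptyFeatureError(ValueError):
    """Raised when a filtering stage leaves no usable features."""


@dataclass
class PipelineConfig:
    """Tunable knobs of the four-stage pipeline.

    ``m_grid`` entries are gene counts or the token ``"all"``; values above
    the available feature count are clipped.  ``learner_grids`` maps each
    learner to its hyperparameter candidates (tuned separately per learner
    on out-of-fold AUC).
    """

    confidence_min: float = 0.99
    variance_min: float = 0.1
    m_grid: tuple = tuple(range(2, 26))
    n_cv_folds: int = 3
    n_repeats: int = 5
    learner_set: tuple[str, ...] = LEARNERS
    learner_grids: Mapping[str, list[dict]] = field(
        default_factory=lambda: dict(DEFAULT_GRIDS)
    )
    seed: int = 0
    mode: str = "celltype"

    def __post_init__(self) -> None:
        ints = [m for m in self.m_grid if m != "all"]
        if ints and min(ints) < 2:
            raise ValueError("m_grid entries must be ≥ 2")
        if self.n_cv_folds < 2:
            raise ValueError("n_cv_folds must be ≥ 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be ≥ 1")
        unknown = set(self.learner_set) - set(LEARNERS)
        if unknown:
            raise ValueError(f"unknown learners {sorted(unknown)}")

    @classmethod
    def fast(cls, **overrides) -> "PipelineConfig":
        """Lightweight screening profile: coarse *m* grid, 3 repeats,
        single-candidate forest/boosting grids.  Same filters, folds and
        ensemble as the default profile, at a fraction of the fits."""
        base = dict(
            m_grid=(2, 4, 8, 15, 25),
            n_repeats=3,
            learner_grids=dict(FAST_GRIDS),
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def for_cci(cls, fast: bool = False, **overrides) -> "PipelineConfig":
        """Profile for binary interaction-activity features: prefiltering is
        skipped, the variance cut-off drops to 0.08, the feature grid runs
        to "all" and the classifier is the random forest alone."""
        base = dict(
            variance_min=0.08,
            m_grid=(2, 4, 8, 16, 32, 64, "all"),
            learner_set=("random_forest",),
            learner_grids={
                "random_forest": (FAST_GRIDS if fast else DEFAULT_GRIDS)["random_forest"]
            },
        )
        if fast:
            base["n_repeats"] = 3
        base.update(overrides)
        return cls(**base)

    @classmethod
    def for_sc(cls, fast: bool = False, **overrides) -> "PipelineConfig":
        """Single-cell-harmonized profile: the *m* grid is widened to 'all'
        to accommodate sparse feature spaces."""
        base = dict(m_grid=tuple(range(2, 26)) + ("all",))
        if fast:
            base.update(
                m_grid=(2, 4, 8, 15, 25, "all"),
                n_repeats=3,
                learner_grids=dict(FAST_GRIDS),
            )
        base.update(overrides)
        return cls(**base)


def _make_learner(name: str, params: dict, random_state: int):
    if name == "logistic":
        return LogisticRegression(
            C=params["C"], solver="liblinear", max_iter=1000,
            random_state=random_state,
        )
    if name == "random_forest":
        return RandomForestClassifier(
            n_estimators=params.get("n_estimators", 200),
            max_depth=params.get("max_depth"),
            random_state=random_state, n_jobs=1,
        )
    if name == "svm":
        return SVC(
            kernel="rbf", C=params["C"], gamma="scale", probability=True,
            random_state=random_state,
        )
    if name == "xgboost":
        return XGBClassifier(
            n_estimators=params.get("n_estimators", 200),
            max_depth=params.get("max_depth", 3),
            learning_rate=params.get("learning_rate", 0.1),
            tree_method="hist", n_jobs=1, random_state=random_state,
            eval_metric="logloss", verbosity=0,
        )
    raise ValueError(f"unknown learner {name!r}")


# ---------------------------------------------------------------------------
# filtering stages
# ---------------------------------------------------------------------------

def confidence_prefilter(
    expr: ExpressionMatrix,
    confidence_column: pd.Series | Mapping[str, float],
    threshold: float = 0.99,
) -> ExpressionMatrix:
    """Stage (a): keep genes deconvolved with confidence ≥ threshold."""
    conf = pd.Series(confidence_column, dtype=float)
    missing = [g for g in expr.gene_ids if g not in conf.index]
    if missing:
        raise ValueError(f"genes without confidence values: {missing[:5]}")
    keep = [g for g in expr.gene_ids if conf[g] >= threshold]
    if not keep:
        name = getattr(confidence_column, "name", None) or "<unnamed>"
        raise EmptyFeatureError(
            f"no genes pass confidence ≥ {threshold} for cell type {name}"
        )
    return expr.subset_genes(keep)


def variance_filter(expr: ExpressionMatrix, threshold: float = 0.1) -> ExpressionMatrix:
    """Stage (b): keep genes with across-sample variance ≥ threshold."""
    if expr.shape[1] < 2:
        raise ValueError("variance filtering needs ≥ 2 samples")
    var = expr.values.var(axis=1, ddof=1)
    keep = list(var.index[var >= threshold])
    if not keep:
        raise EmptyFeatureError(f"no genes pass variance ≥ {threshold}")
    return expr.subset_genes(keep)


def rank_features_anova(X: pd.DataFrame, y: np.ndarray) -> pd.Series:
    """Stage (c) ranking: ANOVA F-scores for association with response.

    ``X`` is samples × genes.  Returns F-scores in descending order; ties
    (including zero-variance genes, scored 0) break lexicographically by
    gene id.  For two groups F equals the squared pooled-variance t
    statistic.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("ANOVA ranking requires both classes present")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Features .* are constant")
        f_scores, _ = f_classif(X.to_numpy(), y)
    f_scores = np.nan_to_num(f_scores, nan=0.0, posinf=np.finfo(float).max)
    scores = pd.Series(f_scores, index=X.columns)
    order = sorted(X.columns, key=lambda g: (-scores[g], g))
    return scores.loc[order]


# ---------------------------------------------------------------------------
# fitted state
# ---------------------------------------------------------------------------

@dataclass
class FoldModel:
    """Frozen per-fold state: selection, scaling and tuned learners."""

    test_sample_ids: list[str]
    features: list[str]
    means: pd.Series
    sds: pd.Series
    models: dict[str, object]
    params: dict[str, dict] = field(default_factory=dict)

    def ensemble_prob(self, X: pd.DataFrame) -> np.ndarray:
        Z = X.reindex(columns=self.features)
        n_missing = int(Z.isna().any().sum())
        if n_missing == len(self.features):
            raise ValueError("all selected genes absent from the new data")
        if n_missing:
            logger.info("imputing %d missing selected gene(s) at training means", n_missing)
            Z = Z.fillna(self.means)
        Z = (Z - self.means) / self.sds
        probs = [
            self.models[name].predict_proba(Z.to_numpy())[:, 1]
            for name in sorted(self.models)
        ]
        return np.mean(probs, axis=0)


@dataclass
class RepeatFit:
    fold_models: list[FoldModel]
    oof_scores: pd.Series


@dataclass
class FittedPredictor:
    """Frozen state of a trained response predictor.

    Holds the per-repeat fold models (selected genes, standardization
    parameters and tuned learners), the averaged out-of-fold training
    scores (min-max rescaled), the rescaling bounds and the PR-optimal
    decision threshold.
    """

    mode: str
    feature_source: str | list[str] | None
    feature_space: list[str]
    training_sample_ids: list[str]
    training_labels: pd.Series
    repeats: list[RepeatFit]
    fitted_scores: pd.Series
    rescale_bounds: tuple[float, float]
    threshold: float
    config: PipelineConfig
    log_transform: bool = True

    @property
    def selected_genes(self) -> list[list[str]]:
        """Per repeat, the union of fold-level selections."""
        out = []
        for rep in self.repeats:
            seen: dict[str, None] = {}
            for fm in rep.fold_models:
                for g in fm.features:
                    seen.setdefault(g)
            out.append(list(seen))
        return out

    @property
    def chosen_m(self) -> list[list[int]]:
        """Per repeat, the inner-CV-selected feature count of each fold."""
        return [[len(fm.features) for fm in rep.fold_models] for rep in self.repeats]

    def oof_auc(self) -> float:
        """AUC of the averaged out-of-fold training scores."""
        return roc_auc(self.fitted_scores.to_numpy(), self.training_labels.to_numpy())


# ---------------------------------------------------------------------------
# core trainer
# ---------------------------------------------------------------------------

def _check_classes(y: np.ndarray, n_folds: int) -> None:
    for cls in (0, 1):
        n = int((y == cls).sum())
        if n < n_folds:
            raise ValueError(
                f"class {cls} has {n} member(s), fewer than {n_folds} CV folds"
            )


def _align(X: pd.DataFrame, y: ResponseLabels) -> tuple[pd.DataFrame, pd.Series]:
    labels = y.align_to(list(X.index)).labels
    return X.loc[labels.index], labels


def _candidate_m(config: PipelineConfig, n_features: int, select_features: bool) -> list[int]:
    if not select_features:
        return [n_features]
    return sorted(
        {min(n_features, n_features if m == "all" else int(m)) for m in config.m_grid}
    )


def _inner_select(
    Xtr: pd.DataFrame,
    ytr: np.ndarray,
    config: PipelineConfig,
    learners: tuple[str, ...],
    select_features: bool,
    rs: int,
) -> tuple[int, dict[str, dict]]:
    """Choose m and per-learner hyperparameters by inner CV on one
    training fold.

    Each learner's candidates are scored by mean inner-fold AUC (ties →
    first candidate); m is then chosen by the mean inner-fold AUC of the
    unweighted ensemble of per-learner winners (ties → smallest m).  If a
    class is too small to split, the smallest m and first candidates are
    used.
    """
    m_values = _candidate_m(config, Xtr.shape[1], select_features)
    fallback = (m_values[0], {n: config.learner_grids[n][0] for n in learners})
    min_class = int(np.bincount(ytr, minlength=2).min())
    if min_class < 2:
        return fallback
    n_inner = min(config.n_cv_folds, min_class)
    only_one_choice = len(m_values) == 1 and all(
        len(config.learner_grids[n]) == 1 for n in learners
    )
    if only_one_choice:
        return m_values[0], {n: config.learner_grids[n][0] for n in learners}

    skf = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=rs)
    folds = list(skf.split(np.zeros(len(ytr)), ytr))
    rankings, scalers = [], []
    for tr, _ in folds:
        if select_features:
            rankings.append(list(rank_features_anova(Xtr.iloc[tr], ytr[tr]).index))
        else:
            rankings.append(list(Xtr.columns))
        mu = Xtr.iloc[tr].mean(axis=0)
        sd = Xtr.iloc[tr].std(axis=0, ddof=0).replace(0.0, 1.0)
        scalers.append((mu, sd))

    best_m, best_auc, best_params = None, -np.inf, None
    for m in m_values:
        # fold-wise probabilities per learner per candidate
        fold_aucs = {n: np.zeros((len(config.learner_grids[n]), len(folds))) for n in learners}
        fold_probs = {n: [[None] * len(folds) for _ in config.learner_grids[n]] for n in learners}
        for fi, (tr, va) in enumerate(folds):
            feats = rankings[fi][:m]
            mu, sd = scalers[fi][0][feats], scalers[fi][1][feats]
            Xa = ((Xtr.iloc[tr][feats] - mu) / sd).to_numpy()
            Xb = ((Xtr.iloc[va][feats] - mu) / sd).to_numpy()
            for name in learners:
                for ci, params in enumerate(config.learner_grids[name]):
                    model = _make_learner(name, params, rs)
                    model.fit(Xa, ytr[tr])
                    p = model.predict_proba(Xb)[:, 1]
                    fold_probs[name][ci][fi] = p
                    fold_aucs[name][ci, fi] = roc_auc(p, ytr[va])
        chosen = {n: int(np.argmax(fold_aucs[n].mean(axis=1))) for n in learners}
        ens_auc = np.mean(
            [
                roc_auc(
                    np.mean([fold_probs[n][chosen[n]][fi] for n in learners], axis=0),
                    ytr[va],
                )
                for fi, (_, va) in enumerate(folds)
            ]
        )
        if ens_auc > best_auc + 1e-12:  # strict improvement; ties keep smallest m
            best_m = m
            best_auc = ens_auc
            best_params = {n: config.learner_grids[n][chosen[n]] for n in learners}
    return (best_m, best_params) if best_m is not None else fallback


def fit_feature_matrix(
    X: pd.DataFrame,
    y: ResponseLabels,
    config: PipelineConfig,
    select_features: bool = True,
    mode: str = "matrix",
    feature_source=None,
    log_transform: bool = False,
) -> FittedPredictor:
    """Train the repeated-CV ensemble on a prepared samples × features matrix.

    This is the shared engine behind every predictor flavor: stages (a)-(b)
    are expected to have been applied by the caller; stage (c) runs inside
    each training fold unless ``select_features`` is False, and stage (d)
    is the configured learner ensemble.
    """
    X, labels = _align(X, y)
    ResponseLabels(labels).require_both_classes()
    yv = labels.to_numpy()
    _check_classes(yv, config.n_cv_folds)
    if X.shape[1] == 0:
        raise EmptyFeatureError("feature matrix has no columns")
    sample_ids = list(X.index)
    learners = tuple(sorted(config.learner_set))

    repeats: list[RepeatFit] = []
    for r in range(config.n_repeats):
        rs = config.seed + r
        skf = StratifiedKFold(n_splits=config.n_cv_folds, shuffle=True, random_state=rs)
        folds = list(skf.split(np.zeros(len(yv)), yv))

        oof = np.empty(len(yv))
        fold_models = []
        for train_idx, test_idx in folds:
            Xtr_df, ytr = X.iloc[train_idx], yv[train_idx]
            m_sel, params_sel = _inner_select(
                Xtr_df, ytr, config, learners, select_features, rs
            )
            if select_features:
                ranking = list(rank_features_anova(Xtr_df, ytr).index)
            else:
                ranking = list(X.columns)
            feats = ranking[:m_sel]
            mu = Xtr_df[feats].mean(axis=0)
            sd = Xtr_df[feats].std(axis=0, ddof=0).replace(0.0, 1.0)
            Xtr = ((Xtr_df[feats] - mu) / sd).to_numpy()
            Xte = ((X.iloc[test_idx][feats] - mu) / sd).to_numpy()
            models, prob_sum = {}, np.zeros(len(test_idx))
            for name in learners:
                model = _make_learner(name, params_sel[name], rs)
                model.fit(Xtr, ytr)
                models[name] = model
                prob_sum += model.predict_proba(Xte)[:, 1]
            oof[test_idx] = prob_sum / len(learners)
            fold_models.append(
                FoldModel(
                    test_sample_ids=[sample_ids[i] for i in test_idx],
                    features=list(feats),
                    means=mu,
                    sds=sd,
                    models=models,
                    params=params_sel,
                )
            )
        repeats.append(
            RepeatFit(
                fold_models=fold_models,
                oof_scores=pd.Series(oof, index=sample_ids),
            )
        )

    raw = pd.concat([rep.oof_scores for rep in repeats], axis=1).mean(axis=1)
    bounds = (float(raw.min()), float(raw.max()))
    fitted = pd.Series(minmax_rescale(raw.to_numpy()), index=sample_ids, name="score")
    threshold = optimal_threshold_from_pr(fitted.to_numpy(), yv)
    return FittedPredictor(
        mode=mode,
        feature_source=feature_source,
        feature_space=list(X.columns),
        training_sample_ids=sample_ids,
        training_labels=labels,
        repeats=repeats,
        fitted_scores=fitted,
        rescale_bounds=bounds,
        threshold=threshold,
        config=config,
        log_transform=log_transform,
    )


# ---------------------------------------------------------------------------
# predictor flavors
# ---------------------------------------------------------------------------

def _celltype_features(
    cohort: DeconvolvedCohort, cell_type: str, config: PipelineConfig
) -> pd.DataFrame:
    expr = cohort.expression[cell_type]
    conf = cohort.confidence_column(cell_type)
    expr = confidence_prefilter(expr, conf, config.confidence_min)
    expr = variance_filter(expr.to_log2(), config.variance_min)
    return expr.values.T


def fit_celltype_predictor(
    cohort: DeconvolvedCohort,
    cell_type: str,
    y: ResponseLabels,
    config: PipelineConfig | None = None,
) -> FittedPredictor:
    """Train a predictor from one cell type's deconvolved expression."""
    config = config or PipelineConfig()
    if cell_type not in cohort.cell_types:
        raise KeyError(f"cell type {cell_type!r} not in cohort")
    X = _celltype_features(cohort, cell_type, config)
    return fit_feature_matrix(
        X, y, config, mode="celltype", feature_source=cell_type, log_transform=True
    )


def multicell_combinations(cell_types: Sequence[str]) -> list[tuple[str, ...]]:
    """All 2- and 3-way cell-type combinations (C(n,2) + C(n,3))."""
    from itertools import combinations

    return [c for k in (2, 3) for c in combinations(cell_types, k)]


def fit_multicell_predictor(
    cohort: DeconvolvedCohort,
    cell_types: Sequence[str],
    y: ResponseLabels,
    config: PipelineConfig | None = None,
) -> FittedPredictor:
    """Train on 2-3 cell types' expression appended as one feature space.

    Each cell type is prefiltered by its own confidence column; gene ids
    are namespaced as ``celltype::gene``; stages (b)-(d) then run on the
    concatenated matrix.
    """
    config = config or PipelineConfig()
    cell_types = list(cell_types)
    if len(set(cell_types)) != len(cell_types):
        raise ValueError("duplicate cell types in multicell list")
    blocks = []
    for ct in cell_types:
        expr = confidence_prefilter(
            cohort.expression[ct], cohort.confidence_column(ct), config.confidence_min
        ).to_log2()
        vals = expr.values.copy()
        vals.index = [f"{ct}::{g}" for g in vals.index]
        blocks.append(vals)
    stacked = ExpressionMatrix(pd.concat(blocks, axis=0), "log2tpm1")
    stacked = variance_filter(stacked, config.variance_min)
    return fit_feature_matrix(
        stacked.values.T, y, config,
        mode="multicell", feature_source=cell_types, log_transform=True,
    )


def fit_bulk_baseline(
    bulk: ExpressionMatrix, y: ResponseLabels, config: PipelineConfig | None = None
) -> FittedPredictor:
    """Bulk-expression baseline: the same pipeline with stage (a) skipped."""
    config = config or PipelineConfig()
    expr = variance_filter(bulk.to_log2(), config.variance_min)
    return fit_feature_matrix(
        expr.values.T, y, config, mode="bulk", feature_source=None, log_transform=True
    )


def fit_fraction_baseline(
    fractions: pd.DataFrame, y: ResponseLabels, config: PipelineConfig | None = None
) -> FittedPredictor:
    """Cell-abundance baseline: stages (a)-(c) skipped, all fractions used."""
    config = config or PipelineConfig()
    if fractions.shape[1] < 2:
        raise ValueError("fraction baseline needs ≥ 2 cell types")
    return fit_feature_matrix(
        fractions, y, config,
        select_features=False, mode="fractions", feature_source=None,
        log_transform=False,
    )


def _new_feature_frame(model: FittedPredictor, new) -> pd.DataFrame:
    if isinstance(new, DeconvolvedCohort):
        if model.mode == "celltype":
            expr = new.expression[model.feature_source]
            return (expr.to_log2() if model.log_transform else expr).values.T
        if model.mode == "multicell":
            blocks = []
            for ct in model.feature_source:
                vals = new.expression[ct].to_log2().values.copy()
                vals.index = [f"{ct}::{g}" for g in vals.index]
                blocks.append(vals)
            return pd.concat(blocks, axis=0).T
        if model.mode == "fractions":
            return new.fractions
        raise ValueError(f"cannot extract {model.mode!r} features from a cohort")
    if isinstance(new, ExpressionMatrix):
        return (new.to_log2() if model.log_transform else new).values.T
    if isinstance(new, pd.DataFrame):
        return new
    raise TypeError(f"unsupported input type {type(new).__name__}")


def predict_scores(model: FittedPredictor, new) -> pd.Series:
    """Score new samples with a fitted predictor.

    Per repeat, each sample is scored by the ensemble of the fold models
    that did not train on it: samples that were part of training receive
    their out-of-fold prediction; unseen samples are scored by every fold
    model and averaged.  Repeat scores are averaged and min-max rescaled
    across the new samples; a constant vector maps to 0.5.  Selected genes
    missing from the new data are imputed at their training means.
    """
    X = _new_feature_frame(model, new)
    sample_ids = list(X.index)
    train_set = set(model.training_sample_ids)

    repeat_scores = []
    for rep in model.repeats:
        fold_probs = []
        fold_masks = []
        for fm in rep.fold_models:
            fold_probs.append(fm.ensemble_prob(X))
            test = set(fm.test_sample_ids)
            fold_masks.append(
                np.array(
                    [(s not in train_set) or (s in test) for s in sample_ids], bool
                )
            )
        P = np.vstack(fold_probs)
        M = np.vstack(fold_masks)
        with np.errstate(invalid="ignore"):
            score = (P * M).sum(axis=0) / M.sum(axis=0)
        repeat_scores.append(score)
    raw = np.mean(repeat_scores, axis=0)
    return pd.Series(minmax_rescale(raw), index=sample_ids, name="score")


# ---------------------------------------------------------------------------
# single-cell harmonization
# ---------------------------------------------------------------------------

def harmonize_sc_expression(
    sc: SingleCellCohort, n_hvg: int = 3500
) -> DeconvolvedCohort:
    """Align single-cell expression with deconvolution-style output.

    Per cell type: the top ``n_hvg`` highly variable genes are picked by
    across-cell variance of log1p expression (ties broken lexicographically)
    and each patient's expression is the mean over their cells of that
    type.  Confidence is 1 everywhere; fractions follow cell counts.
    Patients without cells of a type are absent from that type's matrix.
    """
    cts = sc.cell_type_set
    patients = sc.patients
    if n_hvg > len(sc.gene_ids):
        logger.warning(
            "n_hvg=%d exceeds gene count %d; clipping", n_hvg, len(sc.gene_ids)
        )
        n_hvg = len(sc.gene_ids)

    expression = {}
    counts = pd.DataFrame(0.0, index=patients, columns=cts)
    for t in cts:
        mask = (sc.cell_types == t).to_numpy()
        cells = sc.expression.loc[mask]
        var = np.log1p(cells).var(axis=0, ddof=1)
        hvg = sorted(cells.columns, key=lambda g: (-var[g], g))[:n_hvg]
        cols = {}
        for p in patients:
            pmask = mask & (sc.patient_ids == p).to_numpy()
            counts.loc[p, t] = int(pmask.sum())
            if pmask.any():
                cols[p] = sc.expression.loc[pmask, hvg].mean(axis=0).to_numpy()
        expression[t] = ExpressionMatrix(pd.DataFrame(cols, index=hvg), "tpm")

    fractions = counts.div(counts.sum(axis=1), axis=0)
    genes = sorted(set(g for em in expression.values() for g in em.gene_ids))
    confidence = pd.DataFrame(1.0, index=genes, columns=cts)
    return DeconvolvedCohort(
        cell_types=cts,
        expression=expression,
        confidence=confidence,
        fractions=fractions,
        strict=False,
    )


def pseudobulk_mixture_baseline(
    sc: SingleCellCohort, variance_min: float | None = None
) -> ExpressionMatrix:
    """Per-patient mean expression over all cells, regardless of type.

    The single-cell analog of the bulk mixture.  If ``variance_min`` is
    given, genes below that variance on the log2 scale are dropped.
    """
    cols = {}
    for p in sc.patients:
        mask = (sc.patient_ids == p).to_numpy()
        cols[p] = sc.expression.loc[mask].mean(axis=0).to_numpy()
    em = ExpressionMatrix(pd.DataFrame(cols, index=sc.gene_ids), "tpm")
    if variance_min is not None:
        keep = variance_filter(em.to_log2(), variance_min).gene_ids
        em = em.subset_genes(keep)
    return em
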