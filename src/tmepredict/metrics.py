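"""Scoring and statistics for response predictors.

AUC, average precision, diagnostic odds ratio with a PR-optimized
threshold, one-tailed rank-sum testing, Benjamini-Hochberg adjustment and
Kaplan-Meier / log-rank survival stratification — the full evaluation
vocabulary used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MetricsReport",
    "SurvivalData",
    "roc_auc",
    "average_precision",
    "optimal_threshold_from_pr",
    "diagnostic_odds_ratio",
    "wilcoxon_one_tailed",
    "benjamini_hochberg",
    "km_logrank_stratify",
    "minmax_rescale",
    "compute_metrics",
]


def _as_arrays(scores, y) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    t = np.asarray(y, dtype=int)
    if s.shape != t.shape:
        raise ValueError("scores and labels must have matching length")
    return s, t


def _require_both_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("metric requires both classes present")


def minmax_rescale(scores: np.ndarray) -> np.ndarray:
    """Rescale a score vector to [0, 1]; a constant vector maps to all 0.5."""
    s = np.asarray(scores, dtype=float)
    lo, hi = s.min(), s.max()
    if hi - lo <= 0:
        return np.full_like(s, 0.5)
    return (s - lo) / (hi - lo)


def roc_auc(scores, y) -> float:
    """Area under the ROC curve (ties between classes count one half)."""
    s, t = _as_arrays(scores, y)
    _require_both_classes(t)
    return float(roc_auc_score(t, s))


def average_precision(scores, y) -> float:
    """Average precision: Σ_k (R_k − R_{k−1})·P_k over descending thresholds."""
    s, t = _as_arrays(scores, y)
    _require_both_classes(t)
    return float(average_precision_score(t, s))


def optimal_threshold_from_pr(training_scores, y) -> float:
    """Threshold maximizing F1 along the training precision-recall curve.

    Candidate thresholds are the midpoints between consecutive unique score
    values (predict positive for score ≥ threshold), which keeps the
    returned threshold strictly inside the score range — for rescaled
    training scores, strictly inside (0, 1).  Ties in F1 break toward the
    lowest threshold, which maximizes recall; a constant score vector
    falls back to 0.5.
    """
    s, t = _as_arrays(training_scores, y)
    _require_both_classes(t)
    u = np.unique(s)
    if len(u) < 2:
        return 0.5
    best_f1, best_thr = -1.0, None
    for thr in (u[:-1] + u[1:]) / 2:  # ascending → the lowest tied midpoint wins
        pred = s >= thr
        tp = int(np.sum(pred & (t == 1)))
        fp = int(np.sum(pred & (t == 0)))
        fn = int(np.sum(~pred & (t == 1)))
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1 > best_f1:
            best_f1, best_thr = f1, float(thr)
    return best_thr


def diagnostic_odds_ratio(scores, y, threshold: float) -> float:
    """DOR = (TP·TN)/(FP·FN) after binarizing at ``threshold``.

    Predicted positive means score ≥ threshold.  When any cell of the 2×2
    table is zero, the Haldane-Anscombe +0.5 correction is applied to every
    cell so the ratio stays finite.
    """
    s, t = _as_arrays(scores, y)
    pred = s >= threshold
    tp = float(np.sum(pred & (t == 1)))
    fp = float(np.sum(pred & (t == 0)))
    fn = float(np.sum(~pred & (t == 1)))
    tn = float(np.sum(~pred & (t == 0)))
    if min(tp, fp, fn, tn) == 0:
        tp, fp, fn, tn = tp + 0.5, fp + 0.5, fn + 0.5, tn + 0.5
    return (tp * tn) / (fp * fn)


def wilcoxon_one_tailed(scores_pos, scores_neg) -> float:
    """One-tailed Wilcoxon rank-sum p-value (positive group greater).

    Exact enumeration when the pooled size is ≤ 12 and there are no ties;
    the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(scores_pos, dtype=float)
    b = np.asarray(scores_neg, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="greater", method=method)
    return float(res.pvalue)


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SurvivalData:
    """Right-censored survival outcomes: positive times, binary events."""

    times: pd.Series
    events: pd.Series

    def __post_init__(self) -> None:
        if not self.times.index.equals(self.events.index):
            raise ValueError("times and events must share the sample index")
        if (self.times <= 0).any():
            raise ValueError("survival times must be positive")
        if not set(pd.unique(self.events)) <= {0, 1}:
            raise ValueError("events must be binary")


def km_logrank_stratify(
    scores: pd.Series, surv: SurvivalData, threshold: float = 0.5
) -> tuple[pd.Series, float, dict[str, pd.DataFrame]]:
    """Split samples into High/Low score groups at a fixed threshold.

    High means score strictly greater than ``threshold``.  Returns the group
    assignment, the two-group (Mantel-Haenszel) log-rank p-value, and the
    Kaplan-Meier survival curve per group.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    common = scores.index.intersection(surv.times.index)
    s = scores.loc[common]
    groups = pd.Series(
        np.where(s > threshold, "High", "Low"), index=common, name="group"
    )
    n_high = int((groups == "High").sum())
    if n_high < 2 or len(groups) - n_high < 2:
        raise ValueError(
            f"threshold {threshold} leaves a group with <2 samples "
            f"(High={n_high}, Low={len(groups) - n_high})"
        )
    t, e = surv.times.loc[common], surv.events.loc[common]
    hi, lo = groups == "High", groups == "Low"
    res = logrank_test(t[hi], t[lo], event_observed_A=e[hi], event_observed_B=e[lo])
    curves = {}
    for name, mask in (("High", hi), ("Low", lo)):
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask], label=name)
        curves[name] = kmf.survival_function_
    return groups, float(res.p_value), curves


@dataclass
class MetricsReport:
    """AUC, AP, DOR and rank-sum p for one score vector against labels."""

    auc: float
    average_precision: float
    dor: float
    threshold: float
    wilcoxon_p: float
    n_pos: int
    n_neg: int

    def as_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "average_precision": self.average_precision,
            "dor": self.dor,
            "threshold": self.threshold,
            "wilcoxon_p": self.wilcoxon_p,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


def compute_metrics(scores, y, threshold: float | None = None) -> MetricsReport:
    """Full evaluation of a score vector.

    If ``threshold`` is None the PR-optimal (max-F1) threshold is learned
    from the scores themselves, as done for training scores.
    """
    s, t = _as_arrays(scores, y)
    _require_both_classes(t)
    thr = optimal_threshold_from_pr(s, t) if threshold is None else threshold
    return MetricsReport(
        auc=roc_auc(s, t),
        average_precision=average_precision(s, t),
        dor=diagnostic_odds_ratio(s, t, thr),
        threshold=float(thr),
        wilcoxon_p=wilcoxon_one_tailed(s[t == 1], s[t == 0]),
        n_pos=int((t == 1).sum()),
        n_neg=int((t == 0).sum()),
    )
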