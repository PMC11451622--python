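"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — O(n²) loops, explicit enumeration,
textbook formulas — and shares no code with the package.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, inf, sqrt

import numpy as np


def auc_pairwise(scores, y) -> float:
    """AUC as the fraction of (pos, neg) pairs ranked correctly, ties ½."""
    s = np.asarray(scores, float)
    t = np.asarray(y, int)
    pos = s[t == 1]
    neg = s[t == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def average_precision_step(scores, y) -> float:
    """AP as the step sum Σ (R_k − R_{k−1})·P_k over descending unique scores."""
    s = np.asarray(scores, float)
    t = np.asarray(y, int)
    n_pos = int(t.sum())
    ap, prev_recall = 0.0, 0.0
    for thr in sorted(set(s), reverse=True):
        pred = s >= thr
        tp = int(np.sum(pred & (t == 1)))
        precision = tp / int(pred.sum())
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def bh_stepup(pvals) -> np.ndarray:
    """Benjamini-Hochberg by the textbook step-up formula."""
    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * n / rank)
        adj[i] = running_min
    return adj


def kendall_tau_b_brute(x, y) -> float:
    """Tie-corrected Kendall τ-b by exhaustive pair counting."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    return (conc - disc) / denom if denom else float("nan")


def _tie_term(v) -> float:
    _, counts = np.unique(v, return_counts=True)
    return sum(c * (c - 1) / 2 for c in counts)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Sums the probabilities of all tables with the same margins whose
    probability does not exceed the observed table's (within float slack).
    """
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def table_prob(x: int) -> float:
        return (
            comb(row1, x) * comb(row2, col1 - x) / comb(n, col1)
        )

    p_obs = table_prob(a)
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    total = 0.0
    for x in range(lo, hi + 1):
        p = table_prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def median_rule_activity(expr_by_ct: dict, quads) -> np.ndarray:
    """Median-rule CCI activity by explicit double loops.

    ``expr_by_ct`` maps cell type → genes × samples DataFrame; returns a
    quadruplets × samples 0/1 array.
    """
    first = next(iter(expr_by_ct.values()))
    samples = list(first.columns)
    out = np.zeros((len(quads), len(samples)), dtype=int)
    for qi, q in enumerate(quads):
        lig = expr_by_ct[q.ligand_celltype]
        rec = expr_by_ct[q.receptor_celltype]
        lmed = float(np.median(lig.loc[q.ligand_gene]))
        rmed = float(np.median(rec.loc[q.receptor_gene]))
        for si, s in enumerate(samples):
            if lig.loc[q.ligand_gene, s] > lmed and rec.loc[q.receptor_gene, s] > rmed:
                out[qi, si] = 1
    return out


def wilcoxon_exact_greater(pos, neg) -> float:
    """Exact one-sided rank-sum p by enumerating all group assignments."""
    pos = list(pos)
    neg = list(neg)
    pooled = pos + neg
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    obs = sum(ranks[v] for v in pos)
    count = total = 0
    for subset in combinations(range(len(pooled)), len(pos)):
        stat = sum(ranks[pooled[i]] for i in subset)
        total += 1
        if stat >= obs:
            count += 1
    return count / total


def dor_from_counts(tp, fp, fn, tn) -> float:
    if min(tp, fp, fn, tn) == 0:
        tp, fp, fn, tn = tp + 0.5, fp + 0.5, fn + 0.5, tn + 0.5
    return (tp * tn) / (fp * fn)
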