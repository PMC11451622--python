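"""Deconvolution-accuracy evaluation against ground truth.

Accuracy is scored with Kendall rank correlation (τ-b, tie-corrected):
per cell type across samples for cell fractions, and per (gene, cell type)
across samples for expression, with a two-sided p-value per gene.  Genes
with τ ≥ 0.3 and P ≤ 0.05 count as accurately inferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import DeconvolvedCohort
from .synthetic import BenchmarkCohort

__all__ = [
    "AccuracyReport",
    "kendall_tau",
    "kendall_accuracy",
    "count_accurate_genes",
    "truth_as_cohort",
]


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall τ-b with a two-sided p-value.

    The p-value uses exact enumeration for n ≤ 10 without ties and the
    normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("Kendall τ testing needs at least 3 observations")
    no_ties = len(np.unique(x)) == len(x) and len(np.unique(y)) == len(y)
    method = "exact" if (len(x) <= 10 and no_ties) else "asymptotic"
    res = stats.kendalltau(x, y, variant="b", method=method)
    tau = 0.0 if np.isnan(res.statistic) else float(res.statistic)
    p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    return tau, p


@dataclass
class AccuracyReport:
    """Deconvolution accuracy versus ground truth.

    ``fraction_tau``: τ per cell type across samples (abundance accuracy);
    ``expression_tau`` / ``expression_p``: per-gene, per-cell-type τ and
    two-sided p across samples.
    """

    fraction_tau: pd.Series
    expression_tau: pd.DataFrame
    expression_p: pd.DataFrame

    @property
    def cell_types(self) -> list[str]:
        return list(self.expression_tau.columns)


def kendall_accuracy(
    inferred: DeconvolvedCohort, truth: BenchmarkCohort
) -> AccuracyReport:
    """Score an inferred deconvolution against recorded ground truth."""
    cts = [t for t in inferred.cell_types if t in truth.truth_expression]
    if not cts:
        raise ValueError("no shared cell types between inferred and truth")
    shared = [s for s in inferred.sample_ids if s in truth.truth_fractions.index]
    if len(shared) < 3:
        raise ValueError("need ≥ 3 shared samples for τ testing")

    frac_tau = {}
    for t in cts:
        frac_tau[t] = kendall_tau(
            inferred.fractions.loc[shared, t], truth.truth_fractions.loc[shared, t]
        )[0]

    tau_mat, p_mat = {}, {}
    for t in cts:
        inf = inferred.expression[t].values
        tru = truth.truth_expression[t].values
        genes = [g for g in inf.index if g in tru.index]
        taus = np.empty(len(genes))
        ps = np.empty(len(genes))
        inf_s = inf.loc[genes, shared].to_numpy()
        tru_s = tru.loc[genes, shared].to_numpy()
        for i in range(len(genes)):
            taus[i], ps[i] = kendall_tau(inf_s[i], tru_s[i])
        tau_mat[t] = pd.Series(taus, index=genes)
        p_mat[t] = pd.Series(ps, index=genes)

    return AccuracyReport(
        fraction_tau=pd.Series(frac_tau),
        expression_tau=pd.DataFrame(tau_mat),
        expression_p=pd.DataFrame(p_mat),
    )


def count_accurate_genes(
    report: AccuracyReport, tau_min: float = 0.3, p_max: float = 0.05
) -> dict[str, int]:
    """Count genes with τ ≥ tau_min and P ≤ p_max, per cell type."""
    out = {}
    for t in report.cell_types:
        ok = (report.expression_tau[t] >= tau_min) & (report.expression_p[t] <= p_max)
        out[t] = int(ok.sum())
    return out


def truth_as_cohort(truth: BenchmarkCohort) -> DeconvolvedCohort:
    """Wrap a benchmark cohort's ground truth as a perfect 'inference'.

    Useful as the noiseless upper bound of the benchmark harness: scoring
    it against its own truth yields τ = 1 everywhere.
    """
    cts = list(truth.truth_expression)
    genes = truth.truth_expression[cts[0]].gene_ids
    confidence = pd.DataFrame(1.0, index=genes, columns=cts)
    return DeconvolvedCohort(
        cell_types=cts,
        expression=dict(truth.truth_expression),
        confidence=confidence,
        fractions=truth.truth_fractions.copy(),
    )
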