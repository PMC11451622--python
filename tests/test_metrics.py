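import numpy as np
import pandas as pd
import pytest

import oracles
from tmepredict import (
    SurvivalData,
    average_precision,
    benjamini_hochberg,
    diagnostic_odds_ratio,
    km_logrank_stratify,
    optimal_threshold_from_pr,
    roc_auc,
    wilcoxon_one_tailed,
)
from tmepredict.metrics import minmax_rescale


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_worked_example(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 60))
            y = np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
            s = rng.choice(np.linspace(0, 1, 11), size=n)  # force ties
            assert roc_auc(s, y) == pytest.approx(oracles.auc_pairwise(s, y))

    def test_reversal_complement(self, rng):
        s = rng.random(30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        assert roc_auc(-s, y) == pytest.approx(1 - roc_auc(s, y))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert average_precision([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_matches_step_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 50))
            y = rng.integers(0, 2, n)
            y[:2] = [0, 1]
            s = rng.choice(np.linspace(0, 1, 7), size=n)
            assert average_precision(s, y) == pytest.approx(
                oracles.average_precision_step(s, y)
            )


class TestThresholdAndDor:
    def test_perfect_separation_returns_gap_midpoint(self):
        # F1 = 1 anywhere in the (0.2, 0.8] gap; the lowest candidate
        # midpoint attaining it is the gap midpoint, deterministically
        thr = optimal_threshold_from_pr([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert thr == 0.5

    def test_constant_scores_fall_back_to_half(self):
        assert optimal_threshold_from_pr([0.5, 0.5, 0.5], [0, 1, 1]) == 0.5

    def test_matches_exhaustive_sweep(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 40))
            y = rng.integers(0, 2, n)
            y[:2] = [0, 1]
            s = rng.random(n)
            thr = optimal_threshold_from_pr(s, y)
            # exhaustive oracle: best F1 over all splitting thresholds
            # (the degenerate all-positive rule is not a PR threshold)
            best = max(
                2 * np.sum((s >= t) & (y == 1))
                / (2 * np.sum((s >= t) & (y == 1)) + np.sum((s >= t) & (y == 0)) + np.sum((s < t) & (y == 1)))
                for t in np.unique(s)[1:]
            )
            got = (
                2 * np.sum((s >= thr) & (y == 1))
                / (2 * np.sum((s >= thr) & (y == 1)) + np.sum((s >= thr) & (y == 0)) + np.sum((s < thr) & (y == 1)))
            )
            assert got == pytest.approx(best)

    def test_dor_haldane_corrected_perfect_table(self):
        # TP=TN=5, FP=FN=0 -> (5.5*5.5)/(0.5*0.5) = 121
        s = [0.9] * 5 + [0.1] * 5
        y = [1] * 5 + [0] * 5
        assert diagnostic_odds_ratio(s, y, 0.5) == pytest.approx(121.0)

    def test_dor_monotone_transform_invariance(self, rng):
        s = rng.random(40)
        y = rng.integers(0, 2, 40)
        d1 = diagnostic_odds_ratio(s, y, 0.5)
        d2 = diagnostic_odds_ratio(np.exp(s), y, np.exp(0.5))
        assert d1 == pytest.approx(d2)

    def test_dor_label_swap_reciprocal(self):
        s = [0.9, 0.9, 0.8, 0.2, 0.1, 0.3]
        y = [1, 1, 0, 1, 0, 0]
        d = diagnostic_odds_ratio(s, y, 0.5)
        d_swap = diagnostic_odds_ratio([-v for v in s], y, -0.45)
        assert d_swap == pytest.approx(1 / d)


class TestWilcoxon:
    def test_exact_extreme_arrangement(self):
        # all positives above all negatives: p = 1/C(6,3) = 0.05
        assert wilcoxon_one_tailed([3, 4, 5], [0, 1, 2]) == pytest.approx(0.05)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            vals = rng.normal(size=8)  # continuous: tie-free, exact branch
            pos, neg = vals[:4], vals[4:]
            p = wilcoxon_one_tailed(pos, neg)
            assert p == pytest.approx(oracles.wilcoxon_exact_greater(pos, neg))

    def test_one_sided_complement(self, rng):
        pos = rng.normal(size=5)
        neg = rng.normal(size=6)
        p1 = wilcoxon_one_tailed(pos, neg)
        p2 = wilcoxon_one_tailed(neg, pos)
        assert p1 + p2 >= 1.0


class TestBenjaminiHochberg:
    def test_stepup_hand_case(self):
        assert np.allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        assert np.allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_matches_stepup_oracle(self, rng):
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 50)))
            assert np.allclose(benjamini_hochberg(p), oracles.bh_stepup(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])


class TestSurvival:
    def test_planted_hazard_ratio_detected(self, rng):
        # exponential survival, hazard ratio 3 between groups of 100
        n = 200
        scores = pd.Series(
            np.r_[rng.uniform(0.6, 1.0, 100), rng.uniform(0.0, 0.4, 100)],
            index=[f"s{i}" for i in range(n)],
        )
        hazard = np.where(scores > 0.5, 1.0, 3.0)
        times = rng.exponential(1.0 / hazard)
        cens = rng.exponential(5.0, n)
        surv = SurvivalData(
            times=pd.Series(np.minimum(times, cens) + 1e-9, index=scores.index),
            events=pd.Series((times <= cens).astype(int), index=scores.index),
        )
        groups, p, curves = km_logrank_stratify(scores, surv, threshold=0.5)
        assert (groups == "High").sum() == 100
        assert p <= 0.05
        assert set(curves) == {"High", "Low"}

    def test_degenerate_group_rejected(self, rng):
        scores = pd.Series(rng.uniform(0.6, 1.0, 10), index=[f"s{i}" for i in range(10)])
        surv = SurvivalData(
            times=pd.Series(rng.exponential(1, 10) + 0.01, index=scores.index),
            events=pd.Series(np.ones(10, int), index=scores.index),
        )
        with pytest.raises(ValueError, match="threshold"):
            km_logrank_stratify(scores, surv, threshold=0.5)


def test_minmax_constant_maps_to_half():
    assert np.allclose(minmax_rescale(np.full(5, 3.3)), 0.5)
    out = minmax_rescale(np.array([2.0, 4.0, 3.0]))
    assert out.min() == 0.0 and out.max() == 1.0
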