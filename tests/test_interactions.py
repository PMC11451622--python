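import numpy as np
import pandas as pd
import pytest

import oracles
from tmepredict import (
    CCIQuadruplet,
    LRPairList,
    PipelineConfig,
    PlantedCCI,
    ResponseLabels,
    SingleCellCohort,
    SyntheticSpec,
    cci_directionality,
    cci_feature_importance,
    curate_cci_database,
    enumerate_candidate_ccis,
    fit_cci_predictor,
    generate_deconvolved_fixture,
    generate_pseudopatients,
    generate_sc_cohort,
    infer_cci_activity,
    signed_cci_score,
)
from tmepredict.interactions import CCIActivityMatrix
from tmepredict.metrics import roc_auc


def _pairs(n):
    return LRPairList(tuple((f"L{i}", f"R{i}") for i in range(n)))


class TestEnumeration:
    def test_counts_excluding_self(self):
        quads = enumerate_candidate_ccis(_pairs(134), ["A", "B", "C"], include_self=False)
        assert len(quads) == 804  # 134 × 3 × 2

    def test_degenerate_single_cell_type(self):
        assert enumerate_candidate_ccis(_pairs(1), ["A"], include_self=False) == []
        assert len(enumerate_candidate_ccis(_pairs(1), ["A"], include_self=True)) == 1

    def test_small_inclusive_enumeration(self):
        assert len(enumerate_candidate_ccis(_pairs(2), ["A", "B"], include_self=True)) == 8

    def test_count_formula_property(self, rng):
        for _ in range(10):
            n, k = int(rng.integers(1, 20)), int(rng.integers(1, 6))
            cts = [f"T{i}" for i in range(k)]
            assert len(enumerate_candidate_ccis(_pairs(n), cts, False)) == n * k * (k - 1)
            assert len(enumerate_candidate_ccis(_pairs(n), cts, True)) == n * k * k


def _specific_sc(rng, n_per_type=40):
    """Three cell types; LIG is expressed only in A cells, REC only in B."""
    types = ["A"] * n_per_type + ["B"] * n_per_type + ["C"] * n_per_type
    cells = [f"c{i}" for i in range(len(types))]
    expr = pd.DataFrame(
        rng.lognormal(0, 0.2, size=(len(types), 3)),
        index=cells, columns=["LIG", "REC", "OTHER"],
    )
    expr.loc[[t == "A" for t in types], "LIG"] *= 50
    expr.loc[[t == "B" for t in types], "REC"] *= 50
    return SingleCellCohort(
        expression=expr,
        patient_ids=pd.Series("p1", index=cells),
        cell_types=pd.Series(types, index=cells),
    )


class TestCuration:
    def test_specific_pair_reaches_minimum_p(self, rng):
        sc = _specific_sc(rng)
        lr = LRPairList((("LIG", "REC"),))
        db = curate_cci_database(sc, lr, B=100, seed=0, include_self=False)
        assert db.table.loc["A-B::LIG-REC", "empirical_p"] == pytest.approx(1 / 101)
        assert bool(db.table.loc["A-B::LIG-REC", "likely"])

    def test_constant_expression_is_never_specific(self):
        cells = [f"c{i}" for i in range(30)]
        expr = pd.DataFrame(1.0, index=cells, columns=["LIG", "REC"])
        sc = SingleCellCohort(
            expression=expr,
            patient_ids=pd.Series("p1", index=cells),
            cell_types=pd.Series(["A", "B", "C"] * 10, index=cells),
        )
        db = curate_cci_database(sc, LRPairList((("LIG", "REC"),)), B=50, seed=1)
        assert (db.table["empirical_p"] == 1.0).all()

    def test_pvalues_bounded_below_by_permutation_count(self, rng):
        sc = _specific_sc(rng)
        db = curate_cci_database(sc, _pairs(3).pairs and LRPairList((("LIG", "REC"), ("OTHER", "LIG"))), B=40, seed=2)
        assert (db.table["empirical_p"] >= 1 / 41).all()
        assert (db.table["empirical_p"] <= 1.0).all()

    def test_null_pvalues_roughly_uniform(self, rng):
        # exchangeable expression: empirical p-values should be level
        cells = [f"c{i}" for i in range(90)]
        genes = [f"g{i}" for i in range(40)]
        expr = pd.DataFrame(rng.lognormal(0, 1, (90, len(genes))), index=cells, columns=genes)
        sc = SingleCellCohort(
            expression=expr,
            patient_ids=pd.Series("p1", index=cells),
            cell_types=pd.Series(["A", "B", "C"] * 30, index=cells),
        )
        lr = LRPairList(tuple((genes[2 * i], genes[2 * i + 1]) for i in range(20)))
        db = curate_cci_database(sc, lr, B=99, seed=3)
        frac_likely = db.table["likely"].mean()
        assert frac_likely <= 0.15  # ≈ alpha under the null


class TestActivityRule:
    def test_constant_gene_never_active(self, small_cohort):
        cohort, _ = small_cohort
        ct = cohort.cell_types[0]
        cohort.expression[ct].values.iloc[0, :] = 7.0  # constant gene
        g = cohort.expression[ct].gene_ids[0]
        quad = CCIQuadruplet(ct, g, cohort.cell_types[1], cohort.expression[cohort.cell_types[1]].gene_ids[0])
        act = infer_cci_activity(cohort, [quad])
        assert act.activity.to_numpy().sum() == 0

    def test_matches_brute_force_on_random_fixtures(self, rng):
        from tmepredict.data import DeconvolvedCohort, ExpressionMatrix

        for trial in range(20):
            genes = [f"g{i}" for i in range(20)]
            samples = [f"s{i}" for i in range(15)]
            cts = ["A", "B"]
            expr = {
                t: ExpressionMatrix(
                    pd.DataFrame(rng.choice(np.arange(5.0), size=(20, 15)), index=genes, columns=samples),
                    "tpm",
                )
                for t in cts
            }
            cohort = DeconvolvedCohort(
                cell_types=cts, expression=expr,
                confidence=pd.DataFrame(1.0, index=genes, columns=cts),
                fractions=pd.DataFrame(0.5, index=samples, columns=cts),
            )
            quads = enumerate_candidate_ccis(
                LRPairList(tuple((genes[i], genes[i + 1]) for i in range(0, 10, 2))),
                cts, include_self=True,
            )
            act = infer_cci_activity(cohort, quads)
            expected = oracles.median_rule_activity({t: expr[t].values for t in cts}, quads)
            assert np.array_equal(act.activity.to_numpy(), expected)

    def test_distinct_values_activity_rate_at_most_half(self, rng):
        from tmepredict.data import DeconvolvedCohort, ExpressionMatrix

        genes = ["lg", "rg"]
        samples = [f"s{i}" for i in range(10)]  # even n, all values distinct
        expr = {
            t: ExpressionMatrix(
                pd.DataFrame(
                    rng.permutation(np.arange(20.0)).reshape(2, 10), index=genes, columns=samples
                ),
                "tpm",
            )
            for t in ("A", "B")
        }
        cohort = DeconvolvedCohort(
            cell_types=["A", "B"], expression=expr,
            confidence=pd.DataFrame(1.0, index=genes, columns=["A", "B"]),
            fractions=pd.DataFrame(0.5, index=samples, columns=["A", "B"]),
        )
        act = infer_cci_activity(cohort, [CCIQuadruplet("A", "lg", "B", "rg")])
        assert act.activity.to_numpy().mean() <= 0.5


class TestCciPredictor:
    def test_rare_cci_removed_by_variance_filter(self):
        # active in 1 of 100 samples: Bernoulli variance ≈ 0.0099 < 0.08
        samples = [f"s{i}" for i in range(100)]
        act = pd.DataFrame(0, index=["q1", "q2"], columns=samples, dtype=np.int8)
        act.loc["q1", "s0"] = 1
        act.loc["q2", samples[:50]] = 1  # variance 0.2525, survives
        mat = CCIActivityMatrix(activity=act, quadruplets=[
            CCIQuadruplet("A", "l", "B", "r"), CCIQuadruplet("B", "l", "A", "r"),
        ])
        y = ResponseLabels(pd.Series([1, 0] * 50, index=samples))
        model = fit_cci_predictor(mat, y, PipelineConfig.for_cci(fast=True, n_repeats=2))
        assert model.feature_space == ["q2"]

    def test_label_permutation_gives_chance_auc(self, rng):
        samples = [f"s{i}" for i in range(60)]
        act = pd.DataFrame(
            rng.integers(0, 2, size=(30, 60)).astype(np.int8),
            index=[f"q{i}" for i in range(30)], columns=samples,
        )
        quads = [CCIQuadruplet("A", f"l{i}", "B", f"r{i}") for i in range(30)]
        y = ResponseLabels(pd.Series(rng.permutation([1] * 30 + [0] * 30), index=samples))
        model = fit_cci_predictor(
            CCIActivityMatrix(activity=act, quadruplets=quads), y,
            PipelineConfig.for_cci(fast=True, seed=8),
        )
        assert 0.35 <= model.oof_auc() <= 0.65

    def test_importance_requires_forest_model(self, small_cohort):
        from tmepredict import fit_celltype_predictor

        cohort, labels = small_cohort
        model = fit_celltype_predictor(
            cohort, "myeloid", labels, PipelineConfig.fast(m_grid=(2, 4), n_repeats=1)
        )
        with pytest.raises(ValueError, match="random-forest"):
            cci_feature_importance(model)

    def test_importances_nonnegative_and_informative(self, rng):
        samples = [f"s{i}" for i in range(60)]
        y_vec = np.array([1] * 30 + [0] * 30)
        act = pd.DataFrame(
            rng.integers(0, 2, size=(10, 60)).astype(np.int8),
            index=[f"q{i}" for i in range(10)], columns=samples,
        )
        act.iloc[0] = y_vec  # perfectly predictive quadruplet
        quads = [CCIQuadruplet("A", f"l{i}", "B", f"r{i}") for i in range(10)]
        model = fit_cci_predictor(
            CCIActivityMatrix(activity=act, quadruplets=quads),
            ResponseLabels(pd.Series(y_vec, index=samples)),
            PipelineConfig.for_cci(fast=True, seed=4),
        )
        imp = cci_feature_importance(model)
        assert (imp >= 0).all() and imp.sum() > 0
        assert imp.index[0] == "q0"


class TestDirectionality:
    def _mat(self, arr, y_vec):
        samples = [f"s{i}" for i in range(len(y_vec))]
        act = pd.DataFrame(np.atleast_2d(arr).astype(np.int8),
                           index=[f"q{i}" for i in range(np.atleast_2d(arr).shape[0])],
                           columns=samples)
        quads = [CCIQuadruplet("A", f"l{i}", "B", f"r{i}") for i in range(act.shape[0])]
        return (
            CCIActivityMatrix(activity=act, quadruplets=quads),
            ResponseLabels(pd.Series(y_vec, index=samples)),
        )

    def test_perfectly_enriched_quadruplet_signed_positive(self):
        y_vec = [1] * 10 + [0] * 10
        mat, y = self._mat(np.array(y_vec), y_vec)
        table = cci_directionality(mat, y)
        row = table.iloc[0]
        assert row["sign"] == 1
        assert row["fisher_p"] < 0.05
        assert row["odds_ratio"] > 1

    def test_fisher_p_matches_hypergeometric_oracle(self, rng):
        for _ in range(100):
            y_vec = rng.integers(0, 2, 16)
            y_vec[:2] = [0, 1]
            a_vec = rng.integers(0, 2, 16)
            mat, y = self._mat(a_vec, y_vec)
            table = cci_directionality(mat, y)
            a = int(np.sum((a_vec == 1) & (y_vec == 1)))
            b = int(np.sum((a_vec == 1) & (y_vec == 0)))
            c = int(np.sum((a_vec == 0) & (y_vec == 1)))
            d = int(np.sum((a_vec == 0) & (y_vec == 0)))
            assert table["fisher_p"].iloc[0] == pytest.approx(
                oracles.fisher_two_sided(a, b, c, d), abs=1e-9
            )

    def test_null_activity_rarely_signed(self, rng):
        y_vec = rng.permutation([1] * 20 + [0] * 20)
        arr = rng.integers(0, 2, size=(500, 40))
        mat, y = self._mat(arr, y_vec)
        table = cci_directionality(mat, y)
        raw_rate = (table["fisher_p"] <= 0.05).mean()
        assert raw_rate <= 0.10  # Fisher is conservative; ≈5% or below
        assert (table["sign"] != 0).sum() <= 5  # BH keeps the null quiet


@pytest.fixture(scope="module")
def planted_sc():
    spec = SyntheticSpec(
        n_patients=8, n_genes=30, cell_types=("A-cells", "B-cells2", "C-cells"),
        cells_per_patient_per_type=25,
        planted_ccis=(PlantedCCI("A-cells", "G0001", "B-cells2", "G0002", +1),),
        seed=6,
    )
    return generate_sc_cohort(spec)


class TestPseudopatients:
    def test_exact_group_counts(self, planted_sc):
        quads = [CCIQuadruplet("A-cells", "G0001", "B-cells2", "G0002")]
        pp = generate_pseudopatients(
            planted_sc, planted_sc.patient_labels, quads,
            frac=0.3, reps_per_group=10, B=30, seed=0,
        )
        assert len(pp) == 20
        assert (pp.groups == "R").sum() == 10 and (pp.groups == "NR").sum() == 10

    def test_downsampling_fraction(self, planted_sc):
        quads = [CCIQuadruplet("A-cells", "G0001", "B-cells2", "G0002")]
        pp = generate_pseudopatients(
            planted_sc, planted_sc.patient_labels, quads,
            frac=0.3, reps_per_group=2, B=10, seed=0,
        )
        # 4 patients per group × 25 cells × 3 types = 300 cells; 30% per type
        for pid, cells in pp.cell_subsets.items():
            assert len(cells) == 3 * int(np.floor(0.3 * 100))

    def test_zero_replicates_gives_empty_set(self, planted_sc):
        quads = [CCIQuadruplet("A-cells", "G0001", "B-cells2", "G0002")]
        pp = generate_pseudopatients(
            planted_sc, planted_sc.patient_labels, quads, reps_per_group=0, B=10, seed=0
        )
        assert len(pp) == 0

    def test_subsets_stay_within_their_group(self, planted_sc):
        quads = [CCIQuadruplet("A-cells", "G0001", "B-cells2", "G0002")]
        pp = generate_pseudopatients(
            planted_sc, planted_sc.patient_labels, quads,
            frac=0.3, reps_per_group=5, B=10, seed=1,
        )
        labels = planted_sc.patient_labels.labels
        cell_group = planted_sc.patient_ids.map(labels)
        for pid, cells in pp.cell_subsets.items():
            want = 1 if pp.groups[pid] == "R" else 0
            assert (cell_group.loc[cells] == want).all()

    def test_group_too_small_rejected(self, planted_sc):
        quads = [CCIQuadruplet("A-cells", "G0001", "B-cells2", "G0002")]
        with pytest.raises(ValueError, match="need ≥"):
            generate_pseudopatients(
                planted_sc, planted_sc.patient_labels, quads,
                frac=0.001, reps_per_group=2, B=10, seed=0,
            )


class TestSignedScore:
    def _pp(self, activity, groups):
        keys = list(activity.index)
        quads = [CCIQuadruplet("A", k, "B", k) for k in keys]
        from tmepredict.interactions import PseudoPatientSet

        return PseudoPatientSet(
            groups=pd.Series(groups, index=activity.columns),
            pvalues=activity.astype(float),
            activity=activity,
            cell_subsets={},
            quadruplets=quads,
        )

    def test_all_zero_signs_give_constant_half(self):
        act = pd.DataFrame(
            [[1, 0, 1, 0]], index=["q0"], columns=["R1", "R2", "N1", "N2"], dtype=np.int8
        )
        pp = self._pp(act, ["R", "R", "NR", "NR"])
        directions = pd.DataFrame({"sign": [0]}, index=["q0"])
        assert np.allclose(signed_cci_score(pp, directions), 0.5)

    def test_single_positive_cci_separates_groups(self):
        act = pd.DataFrame(
            [[1, 1, 0, 0]], index=["q0"], columns=["R1", "R2", "N1", "N2"], dtype=np.int8
        )
        pp = self._pp(act, ["R", "R", "NR", "NR"])
        directions = pd.DataFrame({"sign": [1]}, index=["q0"])
        scores = signed_cci_score(pp, directions)
        assert scores.loc[["R1", "R2"]].tolist() == [1.0, 1.0]
        assert scores.loc[["N1", "N2"]].tolist() == [0.0, 0.0]
        assert roc_auc(scores, (pp.groups == "R").astype(int)) == 1.0

    def test_missing_direction_rejected(self):
        act = pd.DataFrame([[1, 0]], index=["q0"], columns=["R1", "N1"], dtype=np.int8)
        pp = self._pp(act, ["R", "NR"])
        with pytest.raises(ValueError, match="missing"):
            signed_cci_score(pp, pd.DataFrame({"sign": []}, index=[]))
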