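import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from subtyperx.errors import AnalysisError
from subtyperx.geneset_scoring import (
    cldn_score,
    filter_expressed,
    geneset_score,
    subtype_score_comparison,
    zscore_by_gene,
)
from subtyperx.io_formats import ExpressionMatrix, GeneSet
from subtyperx.synthetic_data import ExprSimConfig, simulate_expression


class TestZscoreByGene:
    def test_constant_gene_maps_to_zero(self):
        mat = ExpressionMatrix(["g"], ["a", "b", "c"], np.array([[5.0, 5.0, 5.0]]))
        z = zscore_by_gene(mat)
        np.testing.assert_array_equal(z.values, [[0.0, 0.0, 0.0]])

    def test_hand_computed_row(self):
        mat = ExpressionMatrix(["g"], ["a", "b", "c"], np.array([[1.0, 2.0, 3.0]]))
        z = zscore_by_gene(mat)  # sample sd = 1
        np.testing.assert_allclose(z.values, [[-1.0, 0.0, 1.0]])

    def test_rows_mean_zero_sd_one(self, rng):
        mat = ExpressionMatrix(
            [f"g{i}" for i in range(20)],
            [f"s{j}" for j in range(15)],
            rng.lognormal(1.0, 0.5, size=(20, 15)),
        )
        z = zscore_by_gene(mat)
        np.testing.assert_allclose(z.values.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.values.std(axis=1, ddof=1), 1.0, atol=1e-9)
        # sum over samples of each row is 0
        np.testing.assert_allclose(z.values.sum(axis=1), 0.0, atol=1e-9)

    def test_single_sample_errors(self):
        mat = ExpressionMatrix(["g"], ["a"], np.array([[1.0]]))
        with pytest.raises(AnalysisError):
            zscore_by_gene(mat)


class TestGenesetScore:
    def test_antisymmetric_cancellation(self):
        mat = ExpressionMatrix(
            ["g1", "g2"], ["a", "b", "c"],
            np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]),
        )
        sv = geneset_score(mat, GeneSet("S", ["g1", "g2"]), kind="z_sum")
        np.testing.assert_allclose(sv.values, [0.0, 0.0, 0.0], atol=1e-12)

    def test_hand_computed_two_gene_fixture(self):
        mat = ExpressionMatrix(
            ["g1", "g2"], ["a", "b", "c"],
            np.array([[1.0, 2.0, 3.0], [2.0, 2.0, 5.0]]),
        )
        sv = geneset_score(mat, GeneSet("S", ["g1", "g2"]), kind="z_sum")
        np.testing.assert_allclose(
            sv.values, [-1.5774, -0.5774, 2.1547], atol=1e-3
        )

    def test_missing_genes_reported_not_imputed(self, small_expr):
        sv = geneset_score(small_expr, GeneSet("S", ["g1", "NOPE"]), kind="z_sum")
        assert sv.genes_used == ["g1"]
        assert sv.genes_missing == ["NOPE"]

    def test_case_insensitive_matching(self, small_expr):
        sv = geneset_score(small_expr, GeneSet("S", [" G1 "]), kind="raw_sum")
        np.testing.assert_array_equal(sv.values, small_expr.values[0])

    def test_no_genes_present_errors(self, small_expr):
        with pytest.raises(AnalysisError, match="SETX"):
            geneset_score(small_expr, GeneSet("SETX", ["absent"]), kind="z_sum")

    def test_whole_matrix_set_equals_z_sum_of_matrix(self, rng):
        genes = [f"g{i}" for i in range(6)]
        mat = ExpressionMatrix(
            genes, [f"s{j}" for j in range(8)], rng.lognormal(size=(6, 8))
        )
        sv = geneset_score(mat, GeneSet("ALL", genes), kind="z_sum")
        expected = zscore_by_gene(mat).values.sum(axis=0)
        np.testing.assert_allclose(sv.values, expected, atol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(
        a=st.floats(min_value=0.1, max_value=50),
        b=st.floats(min_value=0, max_value=100),
    )
    def test_z_sum_invariant_under_per_gene_affine(self, a, b):
        rng = np.random.default_rng(7)
        values = rng.lognormal(size=(4, 6))
        genes = [f"g{i}" for i in range(4)]
        samples = [f"s{j}" for j in range(6)]
        gs = GeneSet("S", genes[:3])
        base = geneset_score(
            ExpressionMatrix(genes, samples, values), gs, kind="z_sum"
        )
        transformed = geneset_score(
            ExpressionMatrix(genes, samples, a * values + b), gs, kind="z_sum"
        )
        np.testing.assert_allclose(transformed.values, base.values, atol=1e-9)

    def test_raw_sum_additive_over_disjoint_sets(self, rng):
        genes = [f"g{i}" for i in range(6)]
        mat = ExpressionMatrix(
            genes, [f"s{j}" for j in range(5)], rng.lognormal(size=(6, 5))
        )
        a = geneset_score(mat, GeneSet("A", genes[:3]), kind="raw_sum")
        b = geneset_score(mat, GeneSet("B", genes[3:]), kind="raw_sum")
        ab = geneset_score(mat, GeneSet("AB", genes), kind="raw_sum")
        np.testing.assert_allclose(ab.values, a.values + b.values, atol=1e-12)


class TestCldnScore:
    def test_quartet_sum(self, claudin_expr):
        sv = cldn_score(claudin_expr)
        assert sv.values[0] == pytest.approx(10.0)

    def test_all_zero_sample(self, claudin_expr):
        sv = cldn_score(claudin_expr)
        assert sv.values[1] == pytest.approx(0.0)

    def test_claudinlow_plant_recovered(self):
        sets = [GeneSet("CLDNSET", ["CLDN3", "CLDN4", "CLDN7", "CDH1"])]
        cfg = ExprSimConfig(
            n_genes=30,
            n_samples_per_subtype={"ClaudinLow": 25, "Basal": 25, "Luminal": 25},
            gene_sets=sets,
            set_activity={("CLDNSET", "ClaudinLow"): -1.5},
            seed=21,
        )
        mat, ann, _ = simulate_expression(cfg)
        sv = cldn_score(mat)
        means = {}
        for subtype in ("ClaudinLow", "Basal", "Luminal"):
            idx = [i for i, a in enumerate(ann) if a.subtype == subtype]
            means[subtype] = np.mean(sv.values[idx])
        assert means["ClaudinLow"] == min(means.values())


class TestFilterExpressed:
    def test_present_policy(self, small_expr):
        gs = filter_expressed(
            small_expr, ["g1", "g2", "nope1", "nope2"], policy="present"
        )
        assert gs.genes == ["g1", "g2"]

    def test_all_zero_gene_excluded(self):
        mat = ExpressionMatrix(
            ["g1", "g2"], ["a", "b"], np.array([[0.0, 0.0], [1.0, 2.0]])
        )
        gs = filter_expressed(mat, ["g1", "g2"], policy="nonzero_fraction")
        assert gs.genes == ["g2"]

    def test_420_to_408_narrowing(self, rng):
        n_cand, n_zero = 420, 12
        genes = [f"fa{i}" for i in range(n_cand)]
        values = rng.lognormal(1.0, 0.5, size=(n_cand, 30))
        values[:n_zero, :] = 0.0
        mat = ExpressionMatrix(genes, [f"s{j}" for j in range(30)], values)
        gs = filter_expressed(mat, genes)
        assert len(gs) == 408

    def test_empty_candidates_error(self, small_expr):
        with pytest.raises(AnalysisError):
            filter_expressed(small_expr, [])


class TestSubtypeComparison:
    def test_planted_shift_recovered(self):
        sets = [GeneSet("S", [f"t{i}" for i in range(10)])]
        cfg = ExprSimConfig(
            n_genes=60,
            n_samples_per_subtype={"ClaudinLow": 40, "Basal": 40, "Luminal": 40},
            gene_sets=sets,
            set_activity={("S", "ClaudinLow"): 1.0},
            seed=5,
        )
        mat, ann, _ = simulate_expression(cfg)
        sv = geneset_score(mat, sets[0], kind="z_sum")
        summary, anova_p, pairwise = subtype_score_comparison(sv, ann)
        assert anova_p < 1e-6
        top = summary.loc[summary["mean"].idxmax(), "subtype"]
        assert top == "ClaudinLow"
        for pc in pairwise:
            if "ClaudinLow" in pc.pair:
                assert pc.p_adj < 0.05

    def test_null_anova_p_uniform(self):
        # 500 null replicates: ANOVA p on the set score should be ~U(0,1)
        ps = []
        for rep in range(500):
            cfg = ExprSimConfig(
                n_genes=12,
                n_samples_per_subtype={"A": 8, "B": 8, "C": 8},
                gene_sets=[GeneSet("S", [f"t{i}" for i in range(5)])],
                set_activity={},
                seed=1000 + rep,
            )
            mat, ann, _ = simulate_expression(cfg)
            sv = geneset_score(mat, cfg.gene_sets[0], kind="z_sum")
            _, p, _ = subtype_score_comparison(sv, ann)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_tiny_subtype_excluded(self):
        cfg = ExprSimConfig(
            n_genes=12,
            n_samples_per_subtype={"A": 8, "B": 8, "C": 1},
            gene_sets=[GeneSet("S", [f"t{i}" for i in range(5)])],
            seed=2,
        )
        mat, ann, _ = simulate_expression(cfg)
        sv = geneset_score(mat, cfg.gene_sets[0], kind="z_sum")
        summary, _, _ = subtype_score_comparison(sv, ann)
        assert set(summary["subtype"]) == {"A", "B"}
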