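import numpy as np
import pytest
from scipy import stats

from subtyperx.drug_screen import (
    PairwiseComparison,
    classify_specificity,
    one_way_anova,
    pairwise_p_matrix,
    run_screen,
    screen_table,
    standardize,
    tukey_hsd,
)
from subtyperx.errors import AnalysisError, ConfigError
from subtyperx.synthetic_data import PlantedDrugEffect, ScreenSimConfig, simulate_drug_response


class TestOneWayAnova:
    def test_equal_group_means(self):
        f, p = one_way_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_f(self):
        # between-SS 16 on 2 df, within-SS 1.5 on 3 df -> F = 8 / 0.5 = 16
        f, p = one_way_anova([[0, 1], [2, 3], [4, 5]])
        assert f == pytest.approx(16.0)
        assert p == pytest.approx(stats.f.sf(16.0, 2, 3))

    def test_permutation_oracle(self, rng):
        groups = [rng.normal(0.3 * i, 1.0, size=8) for i in range(3)]
        f_obs, p_param = one_way_anova(groups)
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        n_reps, hits = 4000, 0
        for _ in range(n_reps):
            perm = rng.permutation(pooled)
            parts = np.split(perm, np.cumsum(sizes)[:-1])
            f_perm, _ = stats.f_oneway(*parts)
            if f_perm >= f_obs:
                hits += 1
        assert abs(p_param - hits / n_reps) < 0.03

    def test_degenerate_error(self):
        with pytest.raises(AnalysisError, match="degenerate"):
            one_way_anova([[1, 1], [2, 2]])

    def test_too_few_groups(self):
        with pytest.raises(AnalysisError):
            one_way_anova([[1, 2, 3]])

    def test_nan_dropped(self):
        f1, _ = one_way_anova([[0, 1, np.nan], [2, 3], [4, 5]])
        f2, _ = one_way_anova([[0, 1], [2, 3], [4, 5]])
        assert f1 == pytest.approx(f2)


class TestTukey:
    def test_identical_groups_p_one(self):
        out = tukey_hsd([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]], ["A", "B"])
        assert len(out) == 1
        assert out[0].mean_diff == pytest.approx(0.0)
        assert out[0].p_adj == pytest.approx(1.0)

    def test_adjustment_is_conservative(self, rng):
        groups = [rng.normal(m, 1.0, size=6) for m in (0.0, 0.4, 1.0)]
        adj = {pc.pair: pc.p_adj for pc in tukey_hsd(groups, ["A", "B", "C"])}
        for (i, a), (j, b) in [((0, "A"), (1, "B")), ((0, "A"), (2, "C")), ((1, "B"), (2, "C"))]:
            raw = stats.ttest_ind(groups[i], groups[j]).pvalue
            assert adj[(a, b)] >= raw - 1e-12

    def test_canonical_pair_order(self):
        pc = PairwiseComparison("Luminal", "Basal", mean_diff=2.0, p_adj=0.5)
        assert pc.pair == ("Basal", "Luminal")
        assert pc.mean_diff == -2.0

    def test_unbalanced_groups_supported(self, rng):
        groups = [rng.normal(size=4), rng.normal(size=9), rng.normal(size=6)]
        out = tukey_hsd(groups, ["A", "B", "C"])
        assert len(out) == 3
        assert all(0 <= pc.p_adj <= 1 for pc in out)


class TestClassifySpecificity:
    def _pairs(self, p_bh, p_bl, p_lh):
        return [
            PairwiseComparison("Basal", "HER2", -1.0, p_bh),
            PairwiseComparison("Basal", "Luminal", -1.0, p_bl),
            PairwiseComparison("HER2", "Luminal", 0.1, p_lh),
        ]

    def test_printed_basal_specific_example(self):
        # printed Tukey p-values for the included drug
        label = classify_specificity(
            self._pairs(0.0052852, 0.037525, 0.7883976),
            {"Basal": -0.6, "HER2": 0.4, "Luminal": 0.3},
            alpha=0.05,
        )
        assert label == "Basal_specific"

    def test_printed_tendency_only_example(self):
        # one pairwise p above alpha -> not specific
        label = classify_specificity(
            self._pairs(0.0896867, 0.0160972, 0.8032067),
            {"Basal": -0.5, "HER2": 0.2, "Luminal": 0.4},
            alpha=0.05,
        )
        assert label == "none"

    def test_all_p_one(self):
        label = classify_specificity(
            self._pairs(1.0, 1.0, 1.0), {"Basal": -0.5, "HER2": 0.2, "Luminal": 0.4}
        )
        assert label == "none"

    def test_missing_pair_insufficient(self):
        pairs = self._pairs(0.001, 0.001, 0.9)[:2]
        label = classify_specificity(
            pairs, {"Basal": -0.5, "HER2": 0.2, "Luminal": 0.4}
        )
        assert label == "insufficient_data"

    def test_tie_at_minimum_is_none(self):
        label = classify_specificity(
            self._pairs(0.001, 0.001, 0.001),
            {"Basal": -0.5, "HER2": -0.5, "Luminal": 0.4},
        )
        assert label == "none"

    def test_rule_exchangeable_across_subtypes(self):
        # relabeling subtypes permutes the winning label identically
        pairs = [
            PairwiseComparison("HER2", "Basal", -1.0, 0.001),
            PairwiseComparison("HER2", "Luminal", -1.0, 0.001),
            PairwiseComparison("Basal", "Luminal", 0.1, 0.9),
        ]
        label = classify_specificity(
            pairs, {"HER2": -0.6, "Basal": 0.4, "Luminal": 0.3}
        )
        assert label == "HER2_specific"


class TestRunScreen:
    def _sim(self, planted, seed=11, noise_sd=0.5, n=20, n_drugs=30):
        cfg = ScreenSimConfig(
            n_lines_per_subtype={"Basal": n, "HER2": n, "Luminal": n},
            n_drugs=n_drugs,
            planted=planted,
            noise_sd=noise_sd,
            seed=seed,
        )
        return simulate_drug_response(cfg)

    def test_planted_recovery(self):
        planted = [PlantedDrugEffect(f"drug_{i:04d}", "Basal", -1.0) for i in range(5)]
        resp, ann, _ = self._sim(planted)
        results = run_screen(resp, ann)
        labels = {r.drug_id: r.label for r in results}
        assert all(labels[p.drug_id] == "Basal_specific" for p in planted)

    def test_label_invariant_under_constant_shift(self):
        planted = [PlantedDrugEffect("drug_0000", "Basal", -1.0)]
        resp, ann, _ = self._sim(planted)
        before = {r.drug_id: r.label for r in run_screen(resp, ann)}
        resp.z_ic50 = resp.z_ic50 + 5.0
        after = {r.drug_id: r.label for r in run_screen(resp, ann)}
        assert before == after

    def test_sign_flip_moves_label(self):
        resp, ann, _ = self._sim([PlantedDrugEffect("drug_0000", "Basal", -1.5)])
        labels = {r.drug_id: r.label for r in run_screen(resp, ann)}
        assert labels["drug_0000"] == "Basal_specific"
        resp2, ann2, _ = self._sim([PlantedDrugEffect("drug_0000", "Basal", 1.5)])
        labels2 = {r.drug_id: r.label for r in run_screen(resp2, ann2)}
        assert labels2["drug_0000"] != "Basal_specific"

    def test_min_n_gives_insufficient_data(self):
        resp, ann, _ = self._sim([], n=20, n_drugs=3)
        resp.z_ic50[:19, 0] = np.nan  # leave one Basal line only
        results = run_screen(resp, ann, min_n=3)
        labels = {r.drug_id: r.label for r in results}
        assert labels["drug_0000"] == "insufficient_data"
        assert set(labels) == {"drug_0000", "drug_0001", "drug_0002"}  # never dropped

    def test_single_subtype_errors(self):
        cfg = ScreenSimConfig(
            n_lines_per_subtype={"Basal": 5, "HER2": 5}, n_drugs=2, noise_sd=0.5, seed=0
        )
        resp, ann, _ = simulate_drug_response(cfg)
        for a in ann:
            a.subtype = "Basal"
        with pytest.raises(ConfigError):
            run_screen(resp, ann)

    def test_results_sorted_by_anova_p(self):
        resp, ann, _ = self._sim([PlantedDrugEffect("drug_0000", "Basal", -2.0)])
        results = run_screen(resp, ann)
        ps = [r.anova_p for r in results if np.isfinite(r.anova_p)]
        assert ps == sorted(ps)
        assert results[0].drug_id == "drug_0000"

    def test_tables(self):
        resp, ann, _ = self._sim([PlantedDrugEffect("drug_0000", "Basal", -2.0)])
        results = run_screen(resp, ann)
        tab = screen_table(results)
        assert {"drug_id", "anova_p", "label"} <= set(tab.columns)
        pm = pairwise_p_matrix(results)
        assert "Basal-HER2" in pm.columns
        assert pm.loc["drug_0000", "Basal-HER2"] < 0.05

    def test_bh_adjustment_is_stricter_gate(self):
        resp, ann, _ = self._sim([], seed=3, n_drugs=50)
        raw = run_screen(resp, ann, adjust_across_drugs=False)
        adj = run_screen(resp, ann, adjust_across_drugs=True)
        n_raw = sum(1 for r in raw if r.pairwise)
        n_adj = sum(1 for r in adj if r.pairwise)
        assert n_adj <= n_raw


def test_standardize_columns():
    rng = np.random.default_rng(5)
    from subtyperx.io_formats import DrugResponseMatrix

    z = rng.normal(2.0, 3.0, size=(12, 4))
    z[3, 2] = np.nan
    resp = standardize(DrugResponseMatrix(
        [f"L{i}" for i in range(12)], [f"D{j}" for j in range(4)], z
    ))
    for j in range(4):
        col = resp.z_ic50[:, j]
        col = col[np.isfinite(col)]
        assert np.mean(col) == pytest.approx(0.0, abs=1e-9)
        assert np.std(col, ddof=1) == pytest.approx(1.0, abs=1e-9)
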