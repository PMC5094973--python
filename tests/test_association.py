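"""Clustering, PCA, Fisher exact tests, correlation screens, group tests."""

import numpy as np
import pandas as pd
import pytest

import progdyn as pg
from progdyn import ExpressionMatrix, GeneSet, ValidationError
from progdyn.association import FisherResult, fisher_exact

# frozen oracle p-values from R 4.3.3 fisher.test on the same tables
R_3X3 = 0.0133357025   # [[5,1,2],[2,6,1],[1,2,7]]
R_2X3 = 0.0458430458   # [[4,1,0],[1,3,4]]


class TestFisher:
    def test_perfect_independence(self):
        assert fisher_exact([[1, 1], [1, 1]]).p == pytest.approx(1.0)

    def test_2x2_hand_enumeration(self):
        # [[3,0],[0,3]]: 2 of the 20 equally-extreme tables -> 0.1
        assert fisher_exact([[3, 0], [0, 3]]).p == pytest.approx(0.1)

    @pytest.mark.parametrize("table,expected", [
        ([[5, 1, 2], [2, 6, 1], [1, 2, 7]], R_3X3),
        ([[4, 1, 0], [1, 3, 4]], R_2X3),
    ])
    def test_rxc_enumeration_matches_r(self, table, expected):
        res = fisher_exact(table)
        assert res.method == "exact_enumeration"
        assert res.p == pytest.approx(expected, rel=1e-6)

    def test_row_column_permutation_invariance(self):
        base = fisher_exact([[4, 1, 0], [1, 3, 4]]).p
        assert fisher_exact([[1, 3, 4], [4, 1, 0]]).p == pytest.approx(base)
        assert fisher_exact([[0, 1, 4], [4, 3, 1]]).p == pytest.approx(base)

    def test_monte_carlo_converges_to_exact(self):
        table = [[5, 1, 2], [2, 6, 1], [1, 2, 7]]
        res = fisher_exact(table, seed=0, n_sim=20_000, exact_max_total=5)
        assert res.method == "monte_carlo"
        se = np.sqrt(R_3X3 * (1 - R_3X3) / res.n_sim)
        assert abs(res.p - R_3X3) < 3 * se + 2 / res.n_sim

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError, match="margin"):
            fisher_exact([[0, 0], [1, 2]])

    def test_float_coercion(self):
        assert float(FisherResult(p=0.25, method="exact_2x2")) == 0.25


class TestClustering:
    def _block_matrix(self, flip=False):
        # two noise-free sample blocks with opposite set-gene shifts
        genes = [f"u{i}" for i in range(5)] + [f"d{i}" for i in range(5)]
        lo = np.array([5.0] * 5 + [9.0] * 5)
        hi = np.array([9.0] * 5 + [5.0] * 5)
        cols = {}
        for j in range(4):
            cols[f"a{j}"] = hi + 0.01 * j
        for j in range(4):
            cols[f"b{j}"] = lo + 0.01 * j
        values = pd.DataFrame(cols, index=genes)
        if flip:
            values = values[list(values.columns[::-1])]
        ann = pd.Series(["A"] * 4 + ["B"] * 4,
                        index=[f"a{j}" for j in range(4)] + [f"b{j}" for j in range(4)])
        return ExpressionMatrix(values, ann.loc[values.columns])

    def _sets(self):
        return [GeneSet.from_members("S_UP", [f"u{i}" for i in range(5)]),
                GeneSet.from_members("S_DN", [f"d{i}" for i in range(5)])]

    def test_separable_blocks_recovered_and_oriented(self):
        m = self._block_matrix()
        labels = pg.cluster_two_way(m, self._sets())
        # cluster 1 = higher combined score = the up-shifted block
        assert (labels[[f"a{j}" for j in range(4)]] == 1).all()
        assert (labels[[f"b{j}" for j in range(4)]] == 2).all()

    def test_invariant_to_sample_order(self):
        l1 = pg.cluster_two_way(self._block_matrix(), self._sets())
        l2 = pg.cluster_two_way(self._block_matrix(flip=True), self._sets())
        assert (l1.sort_index() == l2.sort_index()).all()

    def test_cohort_clusters_track_classes(self):
        up = GeneSet.from_members("SIG_UP", [f"u{i}" for i in range(50)])
        dn = GeneSet.from_members("SIG_DN", [f"d{i}" for i in range(50)])
        m = pg.generate_cohort(n_normal=20, n_dysplasia=5, n_tumor=30,
                               gene_sets=[up, dn], effect=3.0, noise_sd=0.5,
                               n_background=300, seed=7)
        labels = pg.cluster_two_way(m, [up, dn])
        tab = pg.cluster_class_table(labels, m.annotation)
        assert tab.loc[1, "tumor"] >= 27  # >=90% of tumors in cluster 1
        assert tab.loc[1, "normal"] == 0 if 1 in tab.index else True

    def test_too_few_genes_rejected(self, tiny_matrix):
        with pytest.raises(ValidationError):
            pg.cluster_two_way(tiny_matrix, GeneSet.from_members("S", ["G1"]))


class TestPCA:
    def test_distinct_samples_differ_on_pc1(self, tiny_matrix):
        coords = pg.pca_project(tiny_matrix)
        assert coords.loc["n1", "PC1"] != pytest.approx(coords.loc["t1", "PC1"])

    def test_duplicated_sample_identical_coordinates(self):
        values = pd.DataFrame({"s1": [1.0, 2.0, 5.0], "s2": [1.0, 2.0, 5.0],
                               "s3": [4.0, 0.0, 2.0]}, index=["g1", "g2", "g3"])
        ann = pd.Series(["a", "a", "b"], index=values.columns)
        coords = pg.pca_project(ExpressionMatrix(values, ann))
        assert np.allclose(coords.loc["s1"], coords.loc["s2"])

    def test_variance_ordering(self, rng):
        values = pd.DataFrame(rng.normal(size=(10, 8)),
                              index=[f"g{i}" for i in range(10)],
                              columns=[f"s{i}" for i in range(8)])
        ann = pd.Series(["x"] * 8, index=values.columns)
        coords = pg.pca_project(ExpressionMatrix(values, ann))
        assert coords["PC1"].var() >= coords["PC2"].var()

    def test_constant_matrix_rejected(self):
        values = pd.DataFrame(np.full((3, 3), 2.0),
                              index=list("abc"), columns=list("xyz"))
        ann = pd.Series(["g"] * 3, index=values.columns)
        with pytest.raises(ValidationError):
            pg.pca_project(ExpressionMatrix(values, ann))


class TestCorrelate:
    def test_perfect_and_hand_computed_r(self):
        scores = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        feats = pd.DataFrame({"f1": [1.0, 2.0, 3.0], "f2": [1.0, 3.0, 2.0]},
                             index=["a", "b", "c"])
        out = pg.correlate_scores(scores, feats, screen_p=0.5)
        assert out.loc["f1", "r"] == pytest.approx(1.0)
        assert out.loc["f2", "r"] == pytest.approx(0.5)

    def test_zero_variance_feature_recorded_missing(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        feats = pd.DataFrame({"flat": [2.0] * 4, "ok": [1.0, 2.0, 4.0, 3.0]},
                             index=list("abcd"))
        out = pg.correlate_scores(scores, feats)
        assert np.isnan(out.loc["flat", "r"]) and not out.loc["flat", "hit"]
        assert np.isfinite(out.loc["ok", "p"])

    def test_affine_invariance_and_sign_flip(self, rng):
        scores = pd.Series(rng.normal(size=20), index=[f"s{i}" for i in range(20)])
        f = pd.Series(rng.normal(size=20), index=scores.index)
        base = pg.correlate_scores(scores, f.to_frame("f")).loc["f", "r"]
        pos = pg.correlate_scores(scores, (2 * f + 5).to_frame("f")).loc["f", "r"]
        neg = pg.correlate_scores(scores, (-f).to_frame("f")).loc["f", "r"]
        assert pos == pytest.approx(base, abs=1e-12)
        assert neg == pytest.approx(-base, abs=1e-12)

    def test_missing_feature_values_dropped_per_feature(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        feats = pd.DataFrame({"f": [1.0, np.nan, 3.0, 4.0]}, index=list("abcd"))
        out = pg.correlate_scores(scores, feats)
        assert out.loc["f", "n"] == 3

    def test_negative_hit_flagged_as_sensitivity(self, rng):
        scores = pd.Series(rng.normal(size=51), index=[f"c{i}" for i in range(51)])
        ic50 = pg.generate_drug_response(scores, r_target=0.8, seed=1)
        ic50.index = scores.index
        out = pg.correlate_scores(scores, ic50.to_frame("drug"), screen_p=0.01)
        assert bool(out.loc["drug", "sensitivity"])


class TestCompareGroups:
    def test_mann_whitney_exact_hand_value(self):
        stat, p = pg.compare_groups([1, 2, 3, 4, 5, 6],
                                    ["a"] * 3 + ["b"] * 3, "mann_whitney")
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_groups_t(self):
        stat, p = pg.compare_groups([1, 2, 3, 1, 2, 3],
                                    ["a"] * 3 + ["b"] * 3, "t")
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_kruskal_three_groups_runs(self, rng):
        x = rng.normal(size=30)
        labels = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        stat, p = pg.compare_groups(x, labels, "kruskal_wallis")
        assert 0 <= p <= 1

    @pytest.mark.parametrize("test,labels", [
        ("t", ["a"] * 3 + ["b"] * 3 + ["c"] * 3),      # 3 groups for a 2-group test
        ("mann_whitney", ["a"] * 9),                   # single group
        ("bogus", ["a"] * 4 + ["b"] * 5),              # unknown test
    ])
    def test_wrong_group_count_or_test(self, test, labels):
        with pytest.raises(ValidationError):
            pg.compare_groups(np.arange(9, dtype=float), labels, test)
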