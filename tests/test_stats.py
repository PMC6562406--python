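"""Group tests, Ki-67 correlation, PCA missing-value policy, UPGMA, BH FDR."""

import numpy as np
import pandas as pd
import pytest

from histoptm import stats as hstats


class TestTtest:
    def test_unpaired_pooled_variance_hand_example(self):
        res = hstats.ttest([1, 2, 3], [2, 3, 4])
        assert res.t == pytest.approx(-1.2247, abs=1e-4)
        assert res.p == pytest.approx(0.2878, abs=1e-3)
        assert res.direction == "decrease"

    def test_identical_paired_vectors_convention(self):
        res = hstats.ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert res.t == 0.0 and res.p == 1.0

    def test_insufficient_data_flagged(self):
        res = hstats.ttest([1.0], [2.0, 3.0])
        assert res.tier == "not_computable" and np.isnan(res.p)

    def test_paired_drops_incomplete_pairs(self):
        res = hstats.ttest(
            [1.0, np.nan, 3.0, 4.0], [0.5, 2.0, 2.0, 3.0], paired=True
        )
        assert res.n_a == 3

    def test_two_measurements_demoted_to_light_tier(self):
        # strong effect, but only two values per group
        res = hstats.ttest([1.0, 1.1], [5.0, 5.1])
        assert res.p < 0.05 and res.tier == "light"

    def test_welch_option(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [10.0, 30.0, 50.0]
        pooled = hstats.ttest(a, b, equal_var=True)
        welch = hstats.ttest(a, b, equal_var=False)
        assert pooled.p != welch.p


class TestCompareGroups:
    @pytest.fixture
    def cohort(self):
        m = pd.DataFrame(
            {"f1": [1.0, 1.1, 0.9, 2.1, 2.3, 1.8],
             "f2": [5.0, 5.2, 4.8, 5.1, 4.9, 5.0]},
            index=[f"s{i}" for i in range(6)],
        )
        groups = pd.Series(
            ["normal"] * 3 + ["tumor"] * 3, index=m.index
        )
        pairs = pd.Series([1, 2, 3, 1, 2, 3], index=m.index)
        return m, groups, pairs

    def test_direction_is_a_vs_b(self, cohort):
        m, groups, _ = cohort
        res = hstats.compare_groups(m, groups, "tumor", "normal")
        assert res.loc["f1", "direction"] == "increase"

    def test_paired_matches_by_pair_id(self, cohort):
        m, groups, pairs = cohort
        res = hstats.compare_groups(
            m, groups, "tumor", "normal", paired=True, pairs=pairs
        )
        # paired differences for f1 are exactly +1 each -> very small p
        assert res.loc["f1", "p"] < 0.01

    def test_paired_without_pairs_rejected(self, cohort):
        m, groups, _ = cohort
        with pytest.raises(ValueError):
            hstats.compare_groups(m, groups, "tumor", "normal", paired=True)


class TestPearsonKi67:
    def test_perfect_positive(self):
        out = hstats.pearson_vs_ki67([1, 2, 3, 4], [2, 4, 6, 8])
        assert out["r"] == pytest.approx(1.0)
        assert out["display_flag"]

    def test_negative_not_displayed_under_literal_rule(self):
        out = hstats.pearson_vs_ki67([1, 2, 3, 4], [4, 3, 2, 1])
        assert out["r"] == pytest.approx(-1.0)
        assert not out["display_flag"]
        assert hstats.pearson_vs_ki67(
            [1, 2, 3, 4], [4, 3, 2, 1], absolute=True
        )["display_flag"]

    def test_hand_computed_example(self):
        out = hstats.pearson_vs_ki67([1, 2, 3, 4], [1, 3, 2, 4])
        assert out["r"] == pytest.approx(0.8, abs=1e-9)
        assert out["p"] == pytest.approx(0.2, abs=1e-9)
        assert not out["asterisk"]

    def test_zero_variance_flagged(self):
        out = hstats.pearson_vs_ki67([1.0, 1.0, 1.0], [1, 2, 3])
        assert not out["computable"]

    def test_missing_dropped_pairwise(self):
        out = hstats.pearson_vs_ki67(
            [1, 2, np.nan, 4, 5], [2, 4, 6, 8, 10]
        )
        assert out["n"] == 4 and out["r"] == pytest.approx(1.0)


def oracle_pca_scores(matrix: pd.DataFrame) -> np.ndarray:
    """Independent PCA oracle: eigendecomposition of the covariance matrix."""
    x = matrix.to_numpy() - matrix.to_numpy().mean(axis=0)
    cov = x.T @ x / (len(x) - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    return x @ v[:, order]


class TestPCAPolicy:
    @pytest.fixture
    def groups12(self):
        idx = [f"s{i}" for i in range(12)]
        return pd.Series(["normal"] * 6 + ["tumor"] * 6, index=idx)

    def test_sample_with_11_missing_removed(self, rng, groups12):
        m = pd.DataFrame(
            rng.normal(size=(12, 20)), index=groups12.index
        )
        m.iloc[0, :11] = np.nan
        res = hstats.pca_with_policy(m, groups12)
        assert "s0" not in res.retained_samples

    def test_feature_valid_in_one_group_only_removed(self, rng, groups12):
        m = pd.DataFrame(rng.normal(size=(12, 8)), index=groups12.index)
        m.loc[groups12 == "normal", 3] = np.nan  # tumor-only feature
        res = hstats.pca_with_policy(m, groups12)
        assert 3 not in res.retained_features

    def test_feature_with_six_missing_removed(self, rng, groups12):
        m = pd.DataFrame(rng.normal(size=(12, 8)), index=groups12.index)
        m.iloc[[0, 2, 4, 6, 8, 10], 5] = np.nan
        res = hstats.pca_with_policy(m, groups12)
        assert 5 not in res.retained_features

    def test_complete_matrix_matches_eigendecomposition_oracle(
        self, rng, groups12
    ):
        m = pd.DataFrame(rng.normal(size=(12, 6)), index=groups12.index)
        res = hstats.pca_with_policy(m, groups12)
        oracle = oracle_pca_scores(m)
        got = res.scores.to_numpy()
        for k in range(oracle.shape[1]):
            # eigenvector sign is arbitrary
            assert np.allclose(got[:, k], oracle[:, k], atol=1e-8) or (
                np.allclose(got[:, k], -oracle[:, k], atol=1e-8)
            )

    def test_explained_variance_non_increasing_and_bounded(self, rng, groups12):
        m = pd.DataFrame(rng.normal(size=(12, 6)), index=groups12.index)
        res = hstats.pca_with_policy(m, groups12)
        evr = res.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1 + 1e-9

    def test_too_few_samples_rejected(self, rng):
        m = pd.DataFrame(rng.normal(size=(2, 30)))
        m.iloc[0, :15] = np.nan
        with pytest.raises(ValueError):
            hstats.pca_with_policy(
                m, pd.Series(["a", "b"], index=m.index)
            )


class TestUPGMA:
    def test_three_leaf_hand_case(self):
        # items with correlation distances d12=0.1, d13=d23=0.9:
        # first merge (1,2) at 0.1, then the pair joins 3 at (0.9+0.9)/2
        rng = np.random.default_rng(0)
        base = rng.normal(size=10)
        noise = rng.normal(size=10)
        # construct rows with prescribed correlations via orthogonalization
        b = base - base.mean()
        n = noise - noise.mean()
        n = n - (n @ b) / (b @ b) * b
        b /= np.linalg.norm(b)
        n /= np.linalg.norm(n)
        # rows 1,2 correlate 0.9 with each other (d12 = 0.1); row 3 is
        # orthogonal to row 1 (d13 = 1.0) and nearly so to row 2
        r1 = b
        r2 = 0.9 * b + np.sqrt(1 - 0.81) * n
        m = np.vstack([r1, r2, n])
        df = pd.DataFrame(m, index=["i1", "i2", "i3"])
        res = hstats.hcluster(df, axis="samples")
        # first merge joins i1,i2 (distance 0.1); second height is the average
        # of d13 and d23
        link = res.linkage
        assert set(link[0, :2].astype(int)) == {0, 1}
        assert link[0, 2] == pytest.approx(0.1, abs=1e-9)
        d13 = 1 - np.corrcoef(m[0], m[2])[0, 1]
        d23 = 1 - np.corrcoef(m[1], m[2])[0, 1]
        assert link[1, 2] == pytest.approx((d13 + d23) / 2, abs=1e-9)

    def test_identical_rows_merge_at_zero(self):
        m = pd.DataFrame(
            [[1.0, 2.0, 3.0, 1.5], [2.0, 4.0, 6.0, 3.0], [5.0, 1.0, 2.0, 8.0]],
            index=["a", "b", "c"],
        )
        res = hstats.hcluster(m)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_constant_row_excluded(self):
        m = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]],
            index=["flat", "up", "down"],
        )
        res = hstats.hcluster(m)
        assert res.excluded == ["flat"] and res.labels == ["up", "down"]

    def test_dendrogram_invariant_to_input_order(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 8)),
                         index=list("abcde"))
        res1 = hstats.hcluster(m)
        res2 = hstats.hcluster(m.iloc[::-1])
        n1 = hstats.to_newick(res1)
        n2 = hstats.to_newick(res2)
        # merge heights and leaf sets identical regardless of row order
        assert np.allclose(
            np.sort(res1.linkage[:, 2]), np.sort(res2.linkage[:, 2])
        )
        import re

        leaves = lambda s: sorted(re.findall(r"[a-z]+(?=:)", s))
        assert leaves(n1) == leaves(n2)

    def test_newick_contains_all_labels(self, rng):
        m = pd.DataFrame(rng.normal(size=(4, 6)), index=list("wxyz"))
        nwk = hstats.to_newick(hstats.hcluster(m))
        assert nwk.endswith(";")
        for lab in "wxyz":
            assert lab in nwk


class TestBH:
    def test_step_up_hand_example(self):
        out = hstats.bh_fdr([0.01, 0.02, 0.03])
        assert np.allclose(out["padj"], [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert hstats.bh_fdr([0.2])["padj"].iloc[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert (hstats.bh_fdr([1.0, 1.0, 1.0])["padj"] == 1.0).all()

    def test_monotone_and_at_least_raw(self, rng):
        p = rng.uniform(size=50)
        out = hstats.bh_fdr(p)
        assert (out["padj"] >= out["p"] - 1e-12).all()
        s = out.sort_values("p")["padj"].to_numpy()
        assert np.all(np.diff(s) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hstats.bh_fdr([0.5, 1.5])
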