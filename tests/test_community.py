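"""Alpha diversity, sequential PERMANOVA (with independent oracles), PCoA and
group utilities."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway

from calcmicro import (
    DistanceMatrix,
    Permanova,
    alpha_anova,
    chao1,
    group_compare,
    group_prevalence_filter,
    pairwise_permanova,
    pcoa,
    permanova,
    shannon,
)


class TestAlphaIndices:
    def test_chao1_closed_form(self):
        # S=4, F1=2, F2=1 -> 4 + 2*1/(2*2) = 4.5
        assert chao1([1, 1, 2, 5]) == pytest.approx(4.5)

    def test_chao1_without_rare_classes_equals_richness(self):
        assert chao1([3, 4, 5]) == pytest.approx(3.0)

    def test_shannon_closed_form(self):
        assert shannon([5, 5]) == pytest.approx(np.log(2))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            shannon([0, 0, 0])


class TestAlphaAnova:
    def test_identical_groups_f_zero_p_one(self):
        values = pd.Series([2.0] * 6, index=list("abcdef"))
        groups = pd.Series(["x"] * 3 + ["y"] * 3, index=list("abcdef"))
        res = alpha_anova(values, groups)
        assert res.f == 0.0 and res.pvalue == 1.0

    def test_textbook_two_group_f(self):
        """One-way ANOVA oracle: scipy.f_oneway([1,2,3],[11,12,13]) = 150."""
        values = pd.Series([1, 2, 3, 11, 12, 13], index=list("abcdef"), dtype=float)
        groups = pd.Series(["x"] * 3 + ["y"] * 3, index=list("abcdef"))
        res = alpha_anova(values, groups)
        oracle = f_oneway([1, 2, 3], [11, 12, 13])
        assert res.f == pytest.approx(oracle.statistic)
        assert res.pvalue == pytest.approx(oracle.pvalue)
        assert res.f == pytest.approx(150.0)

    def test_sqrt500_domain_error(self):
        values = pd.Series([100.0, 200.0, 500.0, 120.0], index=list("abcd"))
        groups = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        with pytest.raises(ValueError, match="500"):
            alpha_anova(values, groups, transform="sqrt500")

    def test_small_group_rejected(self):
        values = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        groups = pd.Series(["x", "x", "y"], index=list("abc"))
        with pytest.raises(ValueError, match="fewer than 2"):
            alpha_anova(values, groups)

    def test_tukey_pairs_reported_with_fdr(self):
        rng = np.random.default_rng(0)
        values = pd.Series(rng.normal(0, 1, 18))
        values.iloc[12:] += 4.0
        groups = pd.Series(["a"] * 6 + ["b"] * 6 + ["c"] * 6)
        res = alpha_anova(values, groups, transform="exp")
        assert len(res.tukey) == 3
        assert {"p-adj", "p_fdr"} <= set(res.tukey.columns)


def one_way_f(d: np.ndarray, labels) -> float:
    """Independent one-way PERMANOVA pseudo-F from the classic within-group
    sum-of-squared-distances formula."""
    labels = np.asarray(labels)
    n = len(labels)
    sst = (d[np.triu_indices(n, 1)] ** 2).sum() / n
    ssw = 0.0
    for g in np.unique(labels):
        idx = np.where(labels == g)[0]
        sub = d[np.ix_(idx, idx)]
        ssw += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    ssa = sst - ssw
    a = len(np.unique(labels))
    return (ssa / (a - 1)) / (ssw / (n - a))


class TestPermanova:
    def _univariate(self):
        x = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])
        d = squareform(pdist(x[:, None]))
        ids = list("abcdef")
        meta = pd.DataFrame({"grp": ["lo"] * 3 + ["hi"] * 3}, index=ids)
        return DistanceMatrix(ids, d, "euclidean"), meta

    def test_single_factor_equals_classical_anova_f(self):
        dist, meta = self._univariate()
        res = permanova(dist, meta, ["grp"], n_perm=99, seed=0)
        f_classical = f_oneway([0, 1, 2], [10, 11, 12]).statistic
        assert float(res.table.loc["grp", "F"]) == pytest.approx(f_classical)
        assert f_classical == pytest.approx(150.0)

    def test_r2_partition_sums_to_one(self, study):
        table, meta, _ = study
        calculus = list(meta.calculus_samples())[:20]
        from calcmicro import aitchison_distances

        dist = aitchison_distances(table.select_samples(calculus))
        frame = meta.frame.loc[calculus]
        res = permanova(dist, frame, ["read_count", "dataset", "subspecies"],
                        n_perm=49, seed=1)
        total_r2 = res.r2.sum() + res.residual_r2
        assert total_r2 == pytest.approx(1.0, abs=1e-9)

    def test_sample_order_invariance(self):
        dist, meta = self._univariate()
        order = [3, 0, 4, 1, 5, 2]
        ids = [dist.ids[i] for i in order]
        shuffled = DistanceMatrix(ids, dist.values[np.ix_(order, order)], "euclidean")
        a = Permanova(dist, meta, ["grp"]).fit(permutations="exact")
        b = Permanova(shuffled, meta.loc[ids], ["grp"]).fit(permutations="exact")
        assert float(a.table.loc["grp", "F"]) == pytest.approx(
            float(b.table.loc["grp", "F"])
        )
        assert float(a.table.loc["grp", "p"]) == pytest.approx(
            float(b.table.loc["grp", "p"])
        )

    def test_exact_p_matches_label_enumeration_oracle(self):
        """n=6, two groups of 3: permutation p from full enumeration of all
        720 row/column permutations equals an independent enumeration over
        label assignments of the classic pseudo-F formula."""
        rng = np.random.default_rng(5)
        pts = rng.normal(0, 1, (6, 2))
        pts[3:] += 1.5
        d = squareform(pdist(pts))
        ids = list("abcdef")
        labels = ["g1"] * 3 + ["g2"] * 3
        meta = pd.DataFrame({"grp": labels}, index=ids)
        res = Permanova(DistanceMatrix(ids, d), meta, ["grp"]).fit(permutations="exact")
        f_obs = one_way_f(d, labels)
        count = total = 0
        for perm in itertools.permutations(range(6)):
            perm_labels = [labels[i] for i in perm]
            count += one_way_f(d, perm_labels) >= f_obs - 1e-12
            total += 1
        assert float(res.table.loc["grp", "F"]) == pytest.approx(f_obs)
        assert float(res.table.loc["grp", "p"]) == pytest.approx(count / total)

    def test_agrees_with_skbio_single_factor(self):
        """Cross-check the pseudo-F against scikit-bio's one-way PERMANOVA."""
        import skbio

        rng = np.random.default_rng(2)
        pts = rng.normal(0, 1, (12, 4))
        pts[6:] += 1.0
        d = squareform(pdist(pts))
        ids = [f"s{i}" for i in range(12)]
        grouping = ["a"] * 6 + ["b"] * 6
        meta = pd.DataFrame({"grp": grouping}, index=ids)
        ours = permanova(DistanceMatrix(ids, d), meta, ["grp"], n_perm=99, seed=0)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d, ids=ids), grouping=grouping, permutations=99
        )
        assert float(ours.table.loc["grp", "F"]) == pytest.approx(
            float(theirs["test statistic"])
        )

    def test_rank_deficient_term_rejected(self):
        dist, meta = self._univariate()
        meta = meta.copy()
        meta["dup"] = meta["grp"]
        with pytest.raises(ValueError, match="dup"):
            Permanova(dist, meta, ["grp", "dup"])

    def test_degenerate_distances_give_p_one(self):
        ids = list("abcd")
        d = np.zeros((4, 4))
        meta = pd.DataFrame({"grp": ["x", "x", "y", "y"]}, index=ids)
        res = permanova(DistanceMatrix(ids, d), meta, ["grp"], n_perm=49, seed=0)
        assert float(res.table.loc["grp", "p"]) == 1.0


class TestPairwisePermanova:
    def test_spiked_pair_recovered_and_null_pair_not(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 1, (24, 5))
        pts[16:] += 2.0  # group c differs; a and b exchangeable
        d = squareform(pdist(pts))
        ids = [f"s{i}" for i in range(24)]
        meta = pd.DataFrame({"grp": ["a"] * 8 + ["b"] * 8 + ["c"] * 8}, index=ids)
        out = pairwise_permanova(DistanceMatrix(ids, d), meta, "grp",
                                 n_perm=199, seed=0)
        out = out.set_index(out["group_a"] + "_" + out["group_b"])
        assert out.loc["a_c", "p_adjusted"] < 0.05
        assert out.loc["b_c", "p_adjusted"] < 0.05
        assert out.loc["a_b", "p_adjusted"] > 0.1

    def test_identical_groups_nonsignificant(self):
        d = np.zeros((9, 9))
        ids = [f"s{i}" for i in range(9)]
        meta = pd.DataFrame({"grp": ["a", "b", "c"] * 3}, index=ids)
        out = pairwise_permanova(DistanceMatrix(ids, d), meta, "grp",
                                 n_perm=99, seed=0)
        assert (out["p_adjusted"] >= 0.99).all()


class TestPcoa:
    def test_identical_points_zero_eigenvalues(self):
        d = np.zeros((5, 5))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(5)], d))
        assert np.allclose(res.eigenvalues, 0.0, atol=1e-12)
        assert res.coordinates.shape[1] == 0

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(0, 2, (10, 2))
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(10)], d))
        back = squareform(pdist(res.coordinates.values))
        assert np.allclose(back, d, atol=1e-9)

    def test_eigenvalue_sum_equals_centered_inertia(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(0, 1, (8, 3))
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(8)], d))
        n = 8
        a = -0.5 * d**2
        j = np.eye(n) - np.ones((n, n)) / n
        inertia = np.trace(j @ a @ j)
        assert res.eigenvalues.sum() == pytest.approx(inertia)


class TestGroupPrevalenceFilter:
    def test_inclusive_boundary_and_drops(self):
        counts = pd.DataFrame(
            np.zeros((2, 20), dtype=int),
            index=["boundary", "sparse"],
            columns=[f"s{i}" for i in range(20)],
        )
        groups = pd.Series(["m"] * 10 + ["w"] * 10, index=counts.columns)
        counts.iloc[0, :3] = 1          # 3/10 in group m -> exactly 0.30, kept
        counts.iloc[1, [0, 10]] = 1     # 1/10 in each group -> dropped
        kept = group_prevalence_filter(counts, groups, min_frac=0.30)
        assert kept == ["boundary"]
        assert set(group_prevalence_filter(counts, groups, min_frac=0.0)) == {
            "boundary", "sparse"
        }


class TestGroupCompare:
    def test_wilcoxon_exact_enumeration(self):
        values = pd.DataFrame([[1, 2, 3, 4, 5, 6]], index=["f"],
                              columns=list("abcdef"))
        groups = pd.Series(["x"] * 3 + ["y"] * 3, index=list("abcdef"))
        out = group_compare(values, groups, test="wilcoxon", alternative="less")
        assert out.loc["f", "p"] == pytest.approx(1 / 20)

    def test_welch_on_identical_samples(self):
        values = pd.DataFrame([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], index=["f"],
                              columns=list("abcdef"))
        groups = pd.Series(["x"] * 3 + ["y"] * 3, index=list("abcdef"))
        out = group_compare(values, groups, test="welch_t")
        assert out.loc["f", "p"] == pytest.approx(1.0)

    def test_requires_two_groups(self):
        values = pd.DataFrame([[1, 2, 3]], index=["f"], columns=list("abc"))
        groups = pd.Series(["x", "x", "x"], index=list("abc"))
        with pytest.raises(ValueError, match="two groups"):
            group_compare(values, groups)
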