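import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ribote import assoc


def hypergeom_enumeration(n_universe, n_a, n_b, n_overlap):
    """Oracle: exact P(X >= k) by enumerating C(N, n_b) draws by count."""
    total = math.comb(n_universe, n_b)
    p = 0.0
    for k in range(n_overlap, min(n_a, n_b) + 1):
        p += math.comb(n_a, k) * math.comb(n_universe - n_a, n_b - k) / total
    return p


def wilcoxon_enumeration(g1, g2):
    """Oracle: exact two-sided rank-sum p by enumerating all labelings."""
    pooled = np.concatenate([g1, g2])
    n1 = len(g1)
    ranks = stats.rankdata(pooled)
    obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        total += 1
        s = ranks[list(combo)].sum()
        if abs(s - mu) >= abs(obs - mu) - 1e-9:
            count += 1
    return count / total


class TestCorrelate:
    def test_affine_pearson_one(self):
        x = np.arange(10, dtype=float)
        res = assoc.correlate(x, 2 * x + 1, method="pearson")
        assert res.rho == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_monotone_spearman_one(self):
        x = np.linspace(0.1, 5, 20)
        res = assoc.correlate(x, np.exp(x), method="spearman")
        assert res.rho == pytest.approx(1.0)

    def test_rank_formula_example(self):
        # closed-form rank formula: d^2 = (1,1,1,1,0), sum 4,
        # rho = 1 - 6*4/(5*(25-1)) = 0.8
        res = assoc.correlate([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.rho == pytest.approx(1 - 6 * 4 / (5 * 24))
        assert res.rho == pytest.approx(0.8)

    def test_missing_dropped_pairwise(self):
        x = [1, 2, np.nan, 4, 5, 6]
        y = [2, 4, 5, np.nan, 10, 12]
        res = assoc.correlate(x, y, method="pearson")
        assert res.n == 4
        assert res.rho == pytest.approx(1.0)

    def test_zero_variance_undefined(self):
        res = assoc.correlate([1, 1, 1, 1], [1, 2, 3, 4])
        assert not res.defined
        assert np.isnan(res.rho)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match=">= 3"):
            assoc.correlate([1, 2], [3, 4])

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=50), rng.normal(size=50)
        ours = assoc.correlate(x, y, method="spearman")
        ref = stats.spearmanr(x, y)
        assert ours.rho == pytest.approx(ref.statistic)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-6)


class TestOverlap:
    def test_a_equals_universe_forced(self):
        u = set(range(10))
        res = assoc.overlap_test(u, set(range(4)), u)
        assert res.p_hyper == pytest.approx(1.0)

    def test_worked_5_over_210(self):
        # N=10, |a|=5, |b|=4, overlap=4: p = C(5,4)C(5,0)/C(10,4) = 5/210
        a = set(range(5))
        b = {0, 1, 2, 3}
        res = assoc.overlap_test(a, b, set(range(10)))
        assert res.n_overlap == 4
        assert res.p_hyper == pytest.approx(5 / 210)
        assert res.p_hyper == pytest.approx(hypergeom_enumeration(10, 5, 4, 4))

    def test_enumeration_sweep_small_universes(self):
        for n_u in (4, 7, 12):
            universe = set(range(n_u))
            for n_a in range(1, n_u + 1):
                for n_b in range(1, n_u + 1):
                    for k in range(max(0, n_a + n_b - n_u), min(n_a, n_b) + 1):
                        a = set(range(n_a))
                        b = set(range(k)) | set(range(n_a, n_a + n_b - k))
                        res = assoc.overlap_test(a, b, universe)
                        assert res.p_hyper == pytest.approx(
                            hypergeom_enumeration(n_u, n_a, n_b, k), abs=1e-12)

    def test_monotone_in_overlap(self):
        ps = []
        universe = set(range(40))
        a = set(range(15))
        for k in (3, 6, 9, 12):
            b = set(range(k)) | set(range(15, 15 + 12 - k))
            ps.append(assoc.overlap_test(a, b, universe).p_hyper)
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))

    def test_stray_ids_error(self):
        with pytest.raises(ValueError, match="not contained"):
            assoc.overlap_test({"x"}, set(), {"y"})

    def test_invariants(self):
        res = assoc.overlap_test({1, 2, 3}, {2, 3, 4}, set(range(8)))
        assert res.n_overlap <= min(res.n_a, res.n_b) <= res.n_universe
        assert 0.0 <= res.p_hyper <= 1.0


class TestTwoGroups:
    def test_identical_groups_p_one(self):
        res = assoc.compare_two_groups([1, 2, 3, 1, 2, 3],
                                       ["a", "a", "a", "b", "b", "b"])
        assert res.p == pytest.approx(1.0)

    def test_extreme_separation_exact(self):
        # most extreme of C(6,3)=20 labelings, two-sided -> 2/20 = 0.1
        res = assoc.compare_two_groups([1, 2, 3, 4, 5, 6],
                                       ["a"] * 3 + ["b"] * 3)
        assert res.p == pytest.approx(0.1)
        assert res.p == pytest.approx(
            wilcoxon_enumeration(np.array([1., 2, 3]), np.array([4., 5, 6])))

    def test_label_swap_invariant(self):
        vals = [3.0, 1.0, 4.0, 1.5, 9.0, 2.6]
        labels = ["a", "a", "a", "b", "b", "b"]
        flipped = ["b", "b", "b", "a", "a", "a"]
        assert assoc.compare_two_groups(vals, labels).p == \
            assoc.compare_two_groups(vals, flipped).p

    def test_exact_matches_enumeration_random(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n1, n2 = rng.integers(2, 6, 2)
            g1 = rng.permutation(20)[:n1].astype(float)
            g2 = np.setdiff1d(np.arange(20), g1)[:n2].astype(float)
            res = assoc.compare_two_groups(
                np.concatenate([g1, g2]), ["a"] * n1 + ["b"] * n2)
            assert res.p == pytest.approx(wilcoxon_enumeration(g1, g2))

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            assoc.compare_two_groups([1.0, 2.0], ["a", "a"])


class TestMultiGroups:
    def test_type_one_error_rate(self):
        """Three null groups, vectorized over many reps: F rejects at ~5%."""
        rng = np.random.default_rng(2)
        reps, n = 2000, 8
        g1, g2, g3 = (rng.normal(size=(reps, n)) for _ in range(3))
        _, p = stats.f_oneway(g1, g2, g3, axis=1)
        assert 0.03 < (p < 0.05).mean() < 0.07
        # spot-check our wrapper against one rep
        vals = np.concatenate([g1[0], g2[0], g3[0]])
        labels = ["a"] * n + ["b"] * n + ["c"] * n
        res = assoc.compare_multi_groups(vals, labels)
        assert res.p == pytest.approx(p[0])

    def test_shifted_group_tukey_significant(self):
        rng = np.random.default_rng(3)
        g = rng.normal(size=(3, 10))
        g[2] += 10.0  # +10 SD
        vals = g.ravel()
        labels = np.repeat(["a", "b", "c"], 10)
        res = assoc.compare_multi_groups(vals, labels)
        assert res.pairwise_padj.loc["c", "a"] < 0.001
        assert res.pairwise_padj.loc["c", "b"] < 0.001
        assert res.pairwise_padj.loc["a", "b"] > 0.05

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=18)
        labels = np.repeat(["a", "b", "c"], 6)
        res1 = assoc.compare_multi_groups(vals, labels)
        perm = np.random.default_rng(5).permutation(18)
        res2 = assoc.compare_multi_groups(vals[perm], labels[perm])
        pd.testing.assert_frame_equal(res1.pairwise_padj, res2.pairwise_padj)

    def test_symmetric_table(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=15)
        labels = np.repeat(["a", "b", "c"], 5)
        t = assoc.compare_multi_groups(vals, labels).pairwise_padj
        np.testing.assert_allclose(t.to_numpy(), t.to_numpy().T)

    def test_all_identical_undefined(self):
        res = assoc.compare_multi_groups([1.0] * 9, np.repeat(["a", "b", "c"], 3))
        assert np.isnan(res.statistic)


class TestClustering:
    def test_identical_rows_merge_at_zero(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]],
                         index=["g1", "g2", "g3"])
        out = assoc.cluster_delta_te(m)
        assert out["merge_heights"][0] == pytest.approx(0.0)

    def test_line_points_first_merge(self):
        # points 0, 1, 10 on a line: the 0-1 pair merges first
        m = pd.DataFrame([[0.0], [1.0], [10.0]], index=["a", "b", "c"])
        out = assoc.cluster_delta_te(m)
        link = out["linkage"]
        assert sorted(link[0, :2].astype(int)) == [0, 1]
        assert link[0, 2] == pytest.approx(1.0)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.normal(size=(30, 3)))
        out = assoc.cluster_delta_te(m)
        assert (np.diff(out["merge_heights"]) >= -1e-12).all()

    def test_row_permutation_heights_invariant(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.normal(size=(20, 2)),
                         index=[f"g{i}" for i in range(20)])
        out1 = assoc.cluster_delta_te(m)
        out2 = assoc.cluster_delta_te(m.iloc[::-1])
        np.testing.assert_allclose(sorted(out1["merge_heights"]),
                                   sorted(out2["merge_heights"]))

    def test_missing_imputed_and_flagged(self):
        m = pd.DataFrame([[1.0, np.nan], [0.5, 0.2], [0.1, 0.3]],
                         index=["g1", "g2", "g3"])
        out = assoc.cluster_delta_te(m)
        assert out["imputed_genes"] == ["g1"]

    def test_too_few_rows_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            assoc.cluster_delta_te(pd.DataFrame([[1.0]]))


class TestCompareExternal:
    @staticmethod
    def _te(rng, n=50):
        lfc = rng.normal(size=n)
        p = rng.uniform(size=n)
        return pd.DataFrame({"log2_dte": lfc, "padj": p},
                            index=[f"g{i}" for i in range(n)])

    def test_self_comparison(self):
        rng = np.random.default_rng(9)
        te = self._te(rng)
        res = assoc.compare_external(te, te)
        assert res["correlation"].rho == pytest.approx(1.0)
        # self-overlap attains the minimal possible p given the margins
        up = res["overlap_up"]
        assert up.n_overlap == up.n_a == up.n_b
        assert up.p_hyper == pytest.approx(
            hypergeom_enumeration(up.n_universe, up.n_a, up.n_b, up.n_overlap))

    def test_sign_flip(self):
        rng = np.random.default_rng(10)
        te = self._te(rng)
        flipped = te.copy()
        flipped["log2_dte"] = -flipped["log2_dte"]
        res = assoc.compare_external(te, flipped)
        assert res["correlation"].rho == pytest.approx(-1.0)

    def test_planted_shared_effect_correlation(self):
        """Two datasets sharing a latent effect at rho ~ 0.6."""
        rng = np.random.default_rng(11)
        n = 2000
        shared = rng.normal(size=n)
        a = 0.6 * shared + np.sqrt(1 - 0.36) * rng.normal(size=n)
        b = 0.6 * shared + np.sqrt(1 - 0.36) * rng.normal(size=n)
        # corr(a, b) = 0.36... use construction with direct target instead
        a = shared + rng.normal(size=n) * np.sqrt(1 / 0.6 - 1)
        b = shared + rng.normal(size=n) * np.sqrt(1 / 0.6 - 1)
        # corr(a,b) = 1/(1/0.6) = 0.6
        idx = [f"g{i}" for i in range(n)]
        te = pd.DataFrame({"log2_dte": a, "padj": rng.uniform(size=n)}, index=idx)
        ext = pd.DataFrame({"log2_dte": b, "padj": rng.uniform(size=n)}, index=idx)
        res = assoc.compare_external(te, ext)
        assert 0.5 <= res["correlation"].rho <= 0.7

    def test_empty_intersection_error(self):
        rng = np.random.default_rng(12)
        te = self._te(rng)
        ext = self._te(rng)
        ext.index = [f"h{i}" for i in range(len(ext))]
        with pytest.raises(ValueError, match="no shared genes"):
            assoc.compare_external(te, ext)
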