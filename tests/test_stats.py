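import itertools

import numpy as np
import pandas as pd
import pytest

from oracle_utils import varpart3_fractions
from spongiome.data import DistanceMatrix, InputError, ParameterError
from spongiome import stats


class TestBH:
    def test_monotone_and_bounded(self):
        p = np.array([0.01, 0.04, 0.03, 0.5])
        adj = stats.bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1).all()

    def test_known_example(self):
        adj = stats.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])


class TestDunn:
    def test_identical_groups_z_zero(self):
        vals = [1, 2, 3, 1, 2, 3]
        res = stats.dunn_test(vals, ["a"] * 3 + ["b"] * 3)
        assert res[0].statistic == pytest.approx(0.0)
        assert res[0].p_value == pytest.approx(1.0)

    def test_manual_rank_arithmetic(self):
        # {1,2,3} vs {4,5,6}: Rbar 2 and 5, no ties
        # var_base = 6*7/12 = 3.5; se = sqrt(3.5*(1/3+1/3)); z = -3/se
        res = stats.dunn_test([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        se = np.sqrt(3.5 * (2 / 3))
        assert res[0].statistic == pytest.approx(-3 / se)

    def test_tie_correction_applied(self):
        vals = [1, 1, 1, 2, 2, 2]
        res = stats.dunn_test(vals, ["a", "a", "b", "b", "c", "c"])
        assert all(np.isfinite(r.statistic) for r in res)

    def test_degenerate_rejected(self):
        with pytest.raises(InputError, match="degenerate"):
            stats.dunn_test([5, 5, 5, 5], ["a", "a", "b", "b"])

    def test_bh_applied(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0, 1, 5), rng.normal(3, 1, 5),
                               rng.normal(6, 1, 5)])
        res = stats.dunn_test(vals, ["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        assert all(r.adjusted_p >= r.p_value - 1e-12 for r in res)


class TestPermanova:
    def _separated(self):
        ids = [f"s{i}" for i in range(6)]
        d = np.ones((6, 6))
        d[:3, :3] = 0
        d[3:, 3:] = 0
        np.fill_diagonal(d, 0)
        return DistanceMatrix(ids, d), ["a"] * 3 + ["b"] * 3

    def test_perfect_separation(self):
        dm, groups = self._separated()
        res = stats.permanova(dm, groups, n_permutations=999, seed=0)
        assert np.isinf(res.statistic)
        # exact p equals the fraction of label assignments preserving the
        # partition: 2/20 = 0.1 for 3+3
        assert res.p_value == pytest.approx(0.1, abs=0.03)

    def test_monte_carlo_matches_enumeration(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 3))
        X[3:] += 1.5
        from scipy.spatial.distance import pdist, squareform
        dm = DistanceMatrix([f"s{i}" for i in range(6)],
                            squareform(pdist(X)))
        groups = ["a"] * 3 + ["b"] * 3
        exact = stats.permanova_exhaustive(dm, groups)
        mc = stats.permanova(dm, groups, n_permutations=4999, seed=1)
        assert mc.statistic == pytest.approx(exact.statistic)
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.02)

    def test_group_of_one_rejected(self):
        dm, _ = self._separated()
        with pytest.raises(ParameterError):
            stats.permanova(dm, ["a"] * 5 + ["b"], 99, 0)

    def test_pairwise_skips_singletons(self, caplog):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(7, 2))
        from scipy.spatial.distance import pdist, squareform
        dm = DistanceMatrix([f"s{i}" for i in range(7)], squareform(pdist(X)))
        groups = ["a"] * 3 + ["b"] * 3 + ["c"]
        with caplog.at_level("WARNING"):
            res = stats.pairwise_permanova(dm, groups, 99, 0)
        assert len(res) == 1
        assert res[0].labels == ("a", "b")


class TestMantel:
    def test_self_correlation_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(9, 2))
        from scipy.spatial.distance import pdist, squareform
        dm = DistanceMatrix([str(i) for i in range(9)], squareform(pdist(X)))
        r, p = stats.mantel_test(dm, dm, 99, 0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_spearman_flag(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 2))
        from scipy.spatial.distance import pdist, squareform
        D = squareform(pdist(X))
        dm1 = DistanceMatrix([str(i) for i in range(8)], D)
        dm2 = DistanceMatrix([str(i) for i in range(8)], D ** 2)
        r, _ = stats.mantel_test(dm1, dm2, 99, 0, method="spearman")
        assert r == pytest.approx(1.0)  # monotone transform


class TestEnvPCA:
    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        env = pd.DataFrame({"v1": x, "v2": 2 * x + 1})
        res = stats.env_pca(env)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)
        assert res.contributions["PC1"].to_numpy() == pytest.approx([50, 50])

    def test_identity_covariance_eigenvalues(self):
        rng = np.random.default_rng(1)
        env = pd.DataFrame(rng.normal(size=(4000, 4)),
                           columns=list("abcd"))
        res = stats.env_pca(env)
        eig = res.explained_variance_ratio * 4
        assert np.all(np.abs(eig - 1) < 0.2)

    def test_contributions_sum_100(self):
        rng = np.random.default_rng(2)
        env = pd.DataFrame(rng.normal(size=(15, 5)),
                           columns=list("abcde"))
        res = stats.env_pca(env)
        assert res.contributions.sum(axis=0).to_numpy() == \
            pytest.approx([100] * 5)

    def test_zero_variance_dropped(self, caplog):
        rng = np.random.default_rng(3)
        env = pd.DataFrame({"a": rng.normal(size=10),
                            "b": rng.normal(size=10),
                            "c": np.ones(10)})
        with caplog.at_level("WARNING"):
            res = stats.env_pca(env)
        assert "c" not in res.loadings.index


class TestVIF:
    def test_orthogonal_none_removed(self):
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.normal(size=(20, 4)))
        X = pd.DataFrame(Q, columns=list("abcd"))
        kept, removed = stats.vif_prune(X, 10)
        assert removed == []
        assert list(kept.columns) == list("abcd")

    def test_exact_collinearity_removed_first(self):
        rng = np.random.default_rng(0)
        x1, x2 = rng.normal(size=20), rng.normal(size=20)
        X = pd.DataFrame({"x1": x1, "x2": x2, "x3": x1 + x2})
        kept, removed = stats.vif_prune(X, 10)
        assert len(removed) == 1
        assert removed[0][1] == np.inf
        assert kept.shape[1] == 2

    def test_manual_iteration_oracle(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=40)
        X = pd.DataFrame({
            "p1": base + rng.normal(0, 0.1, 40),
            "p2": base + rng.normal(0, 0.1, 40),
            "p3": base + rng.normal(0, 0.5, 40),
            "p4": rng.normal(size=40),
            "p5": rng.normal(size=40),
        })
        kept, removed = stats.vif_prune(X, 10)
        # independent step-by-step replay with statsmodels-style formula
        cur = X.copy()
        manual_removed = []
        while cur.shape[1] > 1:
            vifs = stats.vif_values(cur)
            if vifs.max() < 10:
                break
            col = next(c for c in cur.columns if vifs[c] == vifs.max())
            manual_removed.append(col)
            cur = cur.drop(columns=[col])
        assert [c for c, _ in removed] == manual_removed
        assert list(kept.columns) == list(cur.columns)
        assert (stats.vif_values(kept) < 10).all()


class TestRDA:
    def test_exact_linear_r2_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        Y = X @ rng.normal(size=(3, 4))
        r2, adj = stats.rda_r2(Y, X)
        assert r2 == pytest.approx(1.0)

    def test_univariate_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=25)
        y = 2 * x + rng.normal(size=25)
        r2, _ = stats.rda_r2(y, x[:, None])
        expect = np.corrcoef(x, y)[0, 1] ** 2
        assert r2 == pytest.approx(expect, abs=1e-10)

    def test_null_adjusted_r2_near_zero(self):
        rng = np.random.default_rng(2)
        vals = []
        for _ in range(500):
            X = rng.normal(size=(20, 3))
            Y = rng.normal(size=(20, 2))
            _, adj = stats.rda_r2(Y, X)
            vals.append(adj)
        assert abs(np.mean(vals)) < 0.02

    def test_underdetermined_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ParameterError):
            stats.rda_r2(rng.normal(size=(4, 2)), rng.normal(size=(4, 3)))

    def test_hellinger_rows_unit_sum_of_squares(self):
        rng = np.random.default_rng(4)
        rel = rng.uniform(0, 1, size=(6, 10))
        H = stats.hellinger(rel)
        assert (H ** 2).sum(axis=1) == pytest.approx(np.ones(6))


class TestVarPart:
    def _sets(self, rng, n=60):
        A = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a1", "a2"])
        B = pd.DataFrame(rng.normal(size=(n, 2)), columns=["b1", "b2"])
        C = pd.DataFrame(rng.normal(size=(n, 2)), columns=["c1", "c2"])
        return A, B, C

    def test_orthogonal_sets(self):
        # exactly orthogonal predictors, noise-free response: each set's
        # unique fraction equals its marginal R2 and nothing is shared
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.normal(size=(60, 4)))
        A = pd.DataFrame(Q[:, :2], columns=["a1", "a2"])
        B = pd.DataFrame(Q[:, 2:], columns=["b1", "b2"])
        Y = 3 * A.to_numpy() @ np.ones((2, 3)) + B.to_numpy() @ np.ones((2, 3))
        vp = stats.variation_partitioning(Y, {"A": A, "B": B},
                                          n_permutations=99, seed=0)
        rA = vp.union_adjusted_r2[frozenset(["A"])]
        rB = vp.union_adjusted_r2[frozenset(["B"])]
        # adjusted-R2 penalty bounds the deviation: (n-1)/(n-m-1) - 1
        tol = (60 - 1) / (60 - 2 - 1) - 1 + 0.01
        assert vp.unique_fractions["A"] == pytest.approx(rA, abs=tol)
        assert vp.unique_fractions["B"] == pytest.approx(rB, abs=tol)
        assert abs(sum(vp.shared_fractions.values())) < tol

    def test_duplicated_set_total_confounding(self):
        rng = np.random.default_rng(1)
        A, _, _ = self._sets(rng)
        B = A.copy()
        B.columns = ["b1", "b2"]
        B[:] = A.to_numpy() + 1e-6 * rng.normal(size=A.shape)
        Y = A.to_numpy() @ np.ones((2, 2)) + 0.2 * rng.normal(size=(60, 2))
        vp = stats.variation_partitioning(Y, {"A": A, "B": B},
                                          n_permutations=99, seed=0)
        assert abs(vp.unique_fractions["A"]) < 0.05
        assert abs(vp.unique_fractions["B"]) < 0.05
        assert vp.shared_fractions[frozenset(["A", "B"])] == pytest.approx(
            vp.full_model_adjusted_r2, abs=0.05)

    def test_three_set_inclusion_exclusion_oracle(self):
        rng = np.random.default_rng(2)
        A, B, C = self._sets(rng)
        Y = (2 * A.to_numpy() @ np.ones((2, 3))
             + B.to_numpy() @ np.ones((2, 3))
             + rng.normal(size=(60, 3)))
        vp = stats.variation_partitioning(Y, {"a": A, "b": B, "c": C},
                                          n_permutations=99, seed=0)
        r2 = {"".join(sorted(k)): v for k, v in (
            ("".join(sorted(S)), v) for S, v in vp.union_adjusted_r2.items())}
        oracle = varpart3_fractions(r2)
        for S, expect in oracle.items():
            assert vp.unique_fractions.get(next(iter(S)), None) == \
                pytest.approx(expect, abs=1e-10) if len(S) == 1 else True
            if len(S) > 1:
                assert vp.shared_fractions[S] == pytest.approx(expect,
                                                               abs=1e-10)

    def test_fractions_sum_to_full_model(self):
        rng = np.random.default_rng(3)
        A, B, C = self._sets(rng, n=40)
        Y = rng.normal(size=(40, 3))
        vp = stats.variation_partitioning(Y, {"A": A, "B": B, "C": C},
                                          n_permutations=99, seed=0)
        total = (sum(vp.unique_fractions.values())
                 + sum(vp.shared_fractions.values()))
        assert total == pytest.approx(vp.full_model_adjusted_r2, abs=1e-10)

    def test_set_label_symmetry(self):
        rng = np.random.default_rng(4)
        A, B, _ = self._sets(rng, n=30)
        Y = A.to_numpy() @ np.ones((2, 2)) + rng.normal(size=(30, 2))
        vp1 = stats.variation_partitioning(Y, {"A": A, "B": B}, 99, 0)
        vp2 = stats.variation_partitioning(Y, {"B": B, "A": A}, 99, 0)
        assert vp1.unique_fractions["A"] == pytest.approx(
            vp2.unique_fractions["A"], abs=1e-12)

    def test_too_many_sets_rejected(self):
        rng = np.random.default_rng(5)
        sets = {f"S{i}": pd.DataFrame(rng.normal(size=(30, 1)),
                                      columns=[f"x{i}"]) for i in range(5)}
        with pytest.raises(ParameterError):
            stats.variation_partitioning(rng.normal(size=(30, 2)), sets)

    def test_overlapping_columns_rejected(self):
        rng = np.random.default_rng(6)
        A = pd.DataFrame(rng.normal(size=(30, 1)), columns=["x"])
        with pytest.raises(ParameterError, match="multiple sets"):
            stats.variation_partitioning(
                rng.normal(size=(30, 2)), {"A": A, "B": A.copy()})
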