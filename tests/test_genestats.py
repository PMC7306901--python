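import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hiertype.genestats import (
    STAT_FUNCS,
    bd_stat,
    bh_adjust,
    dd_stat,
    de_stat,
    dp_stat,
    dv_stat,
    select_top,
)


def two_groups(rng, n_genes=50, n1=30, n2=40):
    X = rng.normal(2.0, 1.0, (n_genes, n1 + n2))
    mask = np.zeros(n1 + n2, dtype=bool)
    mask[:n1] = True
    return X, mask, ~mask, [f"g{i}" for i in range(n_genes)]


class TestBhAdjust:
    def test_step_up_hand_calculation(self):
        assert np.allclose(bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_adjusted_at_least_raw_and_capped(self, rng):
        p = rng.random(200)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)

    def test_sorted_input_monotone(self):
        p = np.sort(np.random.default_rng(1).random(50))
        assert np.all(np.diff(bh_adjust(p)) >= -1e-12)


class TestDeStat:
    def test_constant_gene_degenerate(self, rng):
        X, m1, m2, ids = two_groups(rng)
        X[0, :] = 5.0
        tab = de_stat(X, m1, m2, ids)
        assert tab.loc[0, "statistic"] == 0.0
        assert tab.loc[0, "p_value"] == 1.0

    def test_planted_shift_detected(self, rng):
        X, m1, m2, ids = two_groups(rng, n_genes=200, n1=100, n2=100)
        X[5, m1] += 2.0
        tab = de_stat(X, m1, m2, ids)
        assert tab.loc[5, "adj_p"] < 1e-6
        assert tab.loc[5, "effect"] == pytest.approx(2.0, abs=0.5)
        assert "g5" in select_top(tab, propdiff_cut=-2)

    def test_effect_is_mean_difference(self, rng):
        X, m1, m2, ids = two_groups(rng)
        tab = de_stat(X, m1, m2, ids)
        expected = X[:, m1].mean(axis=1) - X[:, m2].mean(axis=1)
        assert np.allclose(tab["effect"], expected)


class TestDvStat:
    def test_equal_sample_variances_give_zero(self, rng):
        X, m1, m2, ids = two_groups(rng, n1=30, n2=30)
        X[0, m2] = X[0, m1]  # identical values -> identical variances
        tab = dv_stat(X, m1, m2, ids)
        assert tab.loc[0, "statistic"] == pytest.approx(0.0, abs=1e-10)

    def test_matches_scipy_bartlett(self, rng):
        X, m1, m2, ids = two_groups(rng)
        tab = dv_stat(X, m1, m2, ids)
        for g in (0, 10, 49):
            ref = stats.bartlett(X[g, m1], X[g, m2])
            assert tab.loc[g, "statistic"] == pytest.approx(ref.statistic, rel=1e-10)
            assert tab.loc[g, "p_value"] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_variance_ratio_nine_significant(self, rng):
        X, m1, m2, ids = two_groups(rng, n1=50, n2=50)
        X[3, m1] = 2.0 + 3.0 * rng.normal(0, 1, 50)  # sd 3 vs sd 1
        tab = dv_stat(X, m1, m2, ids)
        assert tab.loc[3, "p_value"] < 1e-6

    def test_zero_variance_group_p_one(self, rng):
        X, m1, m2, ids = two_groups(rng)
        X[0, m1] = 1.0
        tab = dv_stat(X, m1, m2, ids)
        assert tab.loc[0, "p_value"] == 1.0


class TestDdStat:
    def test_identical_samples(self, rng):
        X, m1, m2, ids = two_groups(rng, n1=30, n2=30)
        X[0, m2] = X[0, m1]
        tab = dd_stat(X, m1, m2, ids)
        assert tab.loc[0, "statistic"] == pytest.approx(0.0, abs=1e-12)
        assert tab.loc[0, "p_value"] == pytest.approx(1.0)

    def test_disjoint_supports_give_d_one(self, rng):
        X, m1, m2, ids = two_groups(rng)
        X[0, m1] = rng.uniform(0, 1, m1.sum())
        X[0, m2] = rng.uniform(5, 6, m2.sum())
        tab = dd_stat(X, m1, m2, ids)
        assert tab.loc[0, "statistic"] == pytest.approx(1.0)

    def test_d_matches_ecdf_max_gap_oracle(self, rng):
        """Mean-equal variance-different samples: D from the brute-force
        ECDF scan matches the reported statistic."""
        X, m1, m2, ids = two_groups(rng, n1=60, n2=60)
        X[2, m1] = 2.0 + 2.5 * rng.normal(0, 1, m1.sum())
        tab = dd_stat(X, m1, m2, ids)
        a, b = X[2, m1], X[2, m2]
        grid = np.concatenate([a, b])
        gaps = [
            abs((a <= t).mean() - (b <= t).mean()) for t in grid
        ]
        assert tab.loc[2, "statistic"] == pytest.approx(max(gaps), abs=1e-12)
        assert tab.loc[2, "p_value"] < 0.05


class TestDpStat:
    def test_hand_computed_chi_square(self):
        # 2x2 table [[30,10],[10,30]] -> chi2 = 20 without correction
        X = np.zeros((1, 80))
        X[0, :30] = 2.0   # in-group expressed: 30
        X[0, 40:50] = 2.0  # out-group expressed: 10
        m1 = np.zeros(80, dtype=bool)
        m1[:40] = True
        tab = dp_stat(X, m1, ~m1, ["g0"], expr_threshold=1.0)
        assert tab.loc[0, "statistic"] == pytest.approx(20.0)
        assert tab.loc[0, "prop_diff"] == pytest.approx(30 / 40 - 10 / 40)

    def test_equal_proportions_zero(self, rng):
        X = np.zeros((1, 40))
        X[0, :10] = 2.0
        X[0, 20:30] = 2.0
        m1 = np.zeros(40, dtype=bool)
        m1[:20] = True
        tab = dp_stat(X, m1, ~m1, ["g0"])
        assert tab.loc[0, "statistic"] == 0.0
        assert tab.loc[0, "prop_diff"] == 0.0

    def test_degenerate_margin_p_one(self):
        X = np.full((1, 20), 3.0)  # everything expressed
        m1 = np.zeros(20, dtype=bool)
        m1[:10] = True
        tab = dp_stat(X, m1, ~m1, ["g0"])
        assert tab.loc[0, "p_value"] == 1.0


class TestBdStat:
    def test_equal_means_zero(self, rng):
        X = np.tile(np.linspace(0, 4, 30), (1, 1))
        m1 = np.zeros(30, dtype=bool)
        m1[:15] = True
        X = np.vstack([np.concatenate([X[0, :15], X[0, :15]])])
        tab = bd_stat(X, m1, ~m1, ["g0"])
        assert tab.loc[0, "statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_direct_arithmetic(self, rng):
        # m1=3, m2=1, common s=1, p=0.5 -> BI = 2/1 * 0.5 = 1.0
        n = 4000
        vals1 = rng.normal(3.0, 1.0, n)
        vals2 = rng.normal(1.0, 1.0, n)
        X = np.concatenate([vals1, vals2])[np.newaxis, :]
        m1 = np.zeros(2 * n, dtype=bool)
        m1[:n] = True
        tab = bd_stat(X, m1, ~m1, ["g0"])
        assert tab.loc[0, "statistic"] == pytest.approx(1.0, abs=0.05)
        assert tab.loc[0, "adj_p"] == 0.0  # P filter is a no-op for BD

    def test_degenerate_p_boundary(self, rng):
        """p -> 0: a tiny in-group shrinks sqrt(p(1-p)) toward zero."""
        n2 = 400
        X = np.concatenate([[3.0, 3.1], rng.normal(1, 1, n2)])[np.newaxis, :]
        m1 = np.zeros(n2 + 2, dtype=bool)
        m1[:2] = True
        tab = bd_stat(X, m1, ~m1, ["g0"])
        small_p = 2 / (n2 + 2)
        assert tab.loc[0, "statistic"] <= 2.5 * np.sqrt(small_p)


class TestSelectTop:
    def _table(self, adj_p, prop_diff, effect=None, method="DD"):
        n = len(adj_p)
        t = pd.DataFrame(
            {
                "gene_id": [f"g{i:03d}" for i in range(n)],
                "statistic": np.ones(n),
                "p_value": adj_p,
                "adj_p": adj_p,
                "effect": effect if effect is not None else np.full(n, np.nan),
                "prop_diff": prop_diff,
            }
        )
        t.attrs["method"] = method
        return t

    def test_all_failing_gives_empty(self):
        t = self._table(np.full(100, 0.5), np.full(100, 0.2))
        assert select_top(t) == []

    def test_sixty_passing_returns_smallest_fifty(self, rng):
        adj = np.concatenate([np.linspace(1e-6, 0.005, 60), np.full(40, 0.9)])
        t = self._table(adj, np.full(100, 0.2))
        out = select_top(t)
        assert len(out) == 50
        assert out == [f"g{i:03d}" for i in range(50)]

    def test_tie_broken_by_effect_then_gene_id(self):
        adj = np.full(4, 0.001)
        eff = np.array([0.5, 2.0, -3.0, 0.5])
        t = self._table(adj, np.full(4, 0.2), effect=eff)
        out = select_top(t, max_genes=2)
        assert out == ["g002", "g001"]  # |−3| then |2|

    def test_every_returned_gene_passes_cuts(self, rng):
        adj = rng.random(300) * 0.05
        pd_ = rng.uniform(-0.2, 0.3, 300)
        t = self._table(adj, pd_)
        out = select_top(t)
        assert len(out) <= 50
        sub = t.set_index("gene_id").loc[out]
        assert (sub["adj_p"] < 0.01).all()
        assert (sub["prop_diff"].abs() > 0.05).all()

    def test_bd_ranks_by_index_not_p(self):
        t = self._table(np.zeros(5), np.full(5, 0.2), method="BD")
        t["statistic"] = [0.1, 5.0, 3.0, 4.0, 0.2]
        out = select_top(t, max_genes=3)
        assert out == ["g001", "g003", "g002"]

    def test_de_requires_positive_fold_change(self):
        t = self._table(np.full(4, 1e-5), np.full(4, 0.2),
                        effect=np.array([1.0, -1.0, 2.0, -0.1]), method="DE")
        assert select_top(t) == ["g002", "g000"]  # tie on adj_p -> larger |effect| first
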