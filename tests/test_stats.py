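import numpy as np
import pandas as pd
import pytest
import scipy.stats

from metdiary.stats import (
    StatsError,
    anova_from_summary,
    chi_square_table,
    one_way_ancova,
    one_way_anova,
    standardized_regression,
    tukey_hsd,
    two_way_ancova_interaction,
)


def _long(groups: dict) -> pd.DataFrame:
    rows = [{"g": g, "y": v} for g, vals in groups.items() for v in vals]
    return pd.DataFrame(rows)


class TestOneWayAnova:
    def test_hand_computed_f(self):
        # SSB = 6, SSW = 6 -> F = (6/2)/(6/6) = 3, df (2, 6)
        table = _long({"a": [1, 2, 3], "b": [2, 3, 4], "c": [3, 4, 5]})
        r = one_way_anova(table, "y", "g")
        assert r.f_stat == pytest.approx(3.0)
        assert (r.df_between, r.df_within) == (2, 6)

    def test_identical_means_f_near_zero(self):
        table = _long({"a": [1, 2, 3], "b": [2, 1, 3], "c": [3, 2, 1]})
        assert one_way_anova(table, "y", "g").f_stat == pytest.approx(0.0, abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(StatsError):
            one_way_anova(_long({"a": [1], "b": [2, 3]}), "y", "g")

    def test_single_group_rejected(self):
        with pytest.raises(StatsError):
            one_way_anova(_long({"a": [1, 2, 3]}), "y", "g")


class TestAnovaFromSummary:
    def test_matches_raw_anova_on_random_data(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            groups = {
                g: rng.normal(rng.uniform(-1, 1), 1.0, size=rng.integers(3, 30))
                for g in "abcd"
            }
            raw = one_way_anova(_long(groups), "y", "g")
            summ = anova_from_summary(
                [v.mean() for v in groups.values()],
                [v.std(ddof=1) for v in groups.values()],
                [len(v) for v in groups.values()],
            )
            assert summ.f_stat == pytest.approx(raw.f_stat, abs=1e-9)
            assert summ.p_value == pytest.approx(raw.p_value, abs=1e-9)

    def test_equal_means_gives_zero_f(self):
        r = anova_from_summary([5.0, 5.0, 5.0], [1.0, 2.0, 1.5], [10, 12, 9])
        assert r.f_stat == pytest.approx(0.0)

    def test_two_groups_equals_pooled_t_squared(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 15), rng.normal(0.7, 1, 11)
        t, _ = scipy.stats.ttest_ind(a, b)
        r = anova_from_summary(
            [a.mean(), b.mean()], [a.std(ddof=1), b.std(ddof=1)], [len(a), len(b)]
        )
        assert r.f_stat == pytest.approx(t**2, rel=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(StatsError):
            anova_from_summary([1, 2], [1], [5, 5])


class TestAncova:
    def _confounded(self, seed=10, n=900, offsets=(0.0, 0.8, 1.0)):
        rng = np.random.default_rng(seed)
        g = rng.choice(3, size=n)
        # covariate correlated with group membership and outcome
        z = rng.normal(g * 0.5, 1.0)
        y = np.array(offsets)[g] + 2.0 * z + rng.normal(0, 1.0, n)
        return pd.DataFrame({"g": g.astype(str), "z": z, "y": y})

    def test_empty_covariates_reduces_to_anova(self):
        table = self._confounded()
        a = one_way_anova(table, "y", "g")
        c = one_way_ancova(table, "y", "g", [])
        assert c.f_stat == pytest.approx(a.f_stat, abs=1e-9)
        assert c.p_value == pytest.approx(a.p_value, abs=1e-9)
        assert (c.df1, c.df2) == (a.df_between, a.df_within)

    def test_null_covariate_leaves_means_roughly_raw(self):
        rng = np.random.default_rng(11)
        table = pd.DataFrame({
            "g": rng.choice(list("abc"), 600),
            "z": rng.normal(size=600),  # unrelated to y
            "y": rng.normal(size=600),
        })
        c = one_way_ancova(table, "y", "g", ["z"])
        raw = table.groupby("g")["y"].mean()
        for g in "abc":
            assert c.adjusted_means[g] == pytest.approx(raw[g], abs=0.05)

    def test_recovers_known_adjusted_differences(self):
        offsets = (0.0, 0.8, 1.0)
        table = self._confounded(offsets=offsets)
        c = one_way_ancova(table, "y", "g", ["z"])
        d1 = c.adjusted_means["1"] - c.adjusted_means["0"]
        d2 = c.adjusted_means["2"] - c.adjusted_means["0"]
        assert d1 == pytest.approx(0.8, abs=0.25)
        assert d2 == pytest.approx(1.0, abs=0.25)
        # the raw means are confounded upward by z
        raw = table.groupby("g")["y"].mean()
        assert raw["2"] - raw["0"] > d2

    def test_constant_covariate_rejected(self):
        table = self._confounded()
        table["k"] = 1.0
        with pytest.raises(StatsError, match="k"):
            one_way_ancova(table, "y", "g", ["z", "k"])

    def test_collinear_covariates_rejected(self):
        table = self._confounded()
        table["z2"] = 2.0 * table["z"]
        with pytest.raises(StatsError, match="collinear"):
            one_way_ancova(table, "y", "g", ["z", "z2"])


class TestInteraction:
    def _crossed(self, seed=12, n=800, interaction=0.0):
        rng = np.random.default_rng(seed)
        a = rng.choice(["m", "w"], n)
        b = rng.choice(["u", "r"], n)
        y = (
            0.5 * (a == "w")
            + 0.3 * (b == "r")
            + interaction * ((a == "m") & (b == "r"))
            + rng.normal(0, 1.0, n)
        )
        return pd.DataFrame({"a": a, "b": b, "y": y, "z": rng.normal(size=n)})

    def test_factor_order_symmetric(self):
        table = self._crossed(interaction=0.5)
        r1 = two_way_ancova_interaction(table, "y", "a", "b", ["z"])
        r2 = two_way_ancova_interaction(table, "y", "b", "a", ["z"])
        assert r1.f_stat == pytest.approx(r2.f_stat, rel=1e-9)

    def test_detects_one_sided_effect_with_power(self):
        # effect in one factor level only -> interaction; power over seeded reps
        hits = 0
        for seed in range(20):
            table = self._crossed(seed=100 + seed, n=700, interaction=0.6)
            r = two_way_ancova_interaction(table, "y", "a", "b", ["z"])
            hits += r.p_value < 0.05
        assert hits >= 16  # power > 0.8

    def test_empty_cell_rejected(self):
        table = self._crossed()
        table = table[~((table.a == "m") & (table.b == "r"))]
        with pytest.raises(StatsError, match="cell"):
            two_way_ancova_interaction(table, "y", "a", "b", [])


class TestTukey:
    def test_two_groups_matches_anova_p(self):
        rng = np.random.default_rng(13)
        table = _long({"a": rng.normal(0, 1, 20), "b": rng.normal(0.8, 1, 25)})
        t = tukey_hsd(table, "y", "g")
        a = one_way_anova(table, "y", "g")
        (_, p_adj), = t.pairwise.values()
        assert p_adj == pytest.approx(a.p_value, abs=1e-4)

    def test_identical_groups_p_near_one(self):
        x = np.arange(30, dtype=float)
        table = _long({"a": x, "b": x, "c": x})
        for _, p in tukey_hsd(table, "y", "g").pairwise.values():
            assert p > 0.95

    def test_graded_offsets_order_pairwise_p(self):
        rng = np.random.default_rng(14)
        table = _long({
            "urban": rng.normal(0.0, 1, 300),
            "urban_rural": rng.normal(0.25, 1, 150),
            "rural": rng.normal(0.5, 1, 220),
        })
        t = tukey_hsd(table, "y", "g")
        ps = {frozenset(k): p for k, (_, p) in t.pairwise.items()}
        assert ps[frozenset(("urban", "rural"))] == min(ps.values())

    def test_needs_two_groups(self):
        with pytest.raises(StatsError):
            tukey_hsd(_long({"a": [1, 2, 3]}), "y", "g")


class TestChiSquare:
    def test_proportional_table_is_null(self):
        row = np.array([2.0, 3.0, 5.0])
        counts = np.outer([1.0, 2.0], row) * 10
        stat, df, p = chi_square_table(counts)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert df == 2 and p == pytest.approx(1.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(15)
        counts = rng.integers(5, 60, size=(4, 3)).astype(float)
        s1, _, _ = chi_square_table(counts)
        s2, _, _ = chi_square_table(counts[::-1, ::-1])
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(StatsError):
            chi_square_table([[0, 0], [3, 4]])

    def test_df_formula(self):
        _, df, _ = chi_square_table(np.ones((5, 3)) * 4)
        assert df == 8


class TestStandardizedRegression:
    def test_single_predictor_beta_is_pearson_r(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=200)
        y = 0.6 * x + rng.normal(size=200)
        table = pd.DataFrame({"x": x, "y": y})
        res = standardized_regression(table, "y", ["x"])
        r = np.corrcoef(x, y)[0, 1]
        assert res.standardized_betas["x"] == pytest.approx(r, abs=1e-12)

    def test_exact_sum_gives_r2_one(self):
        rng = np.random.default_rng(17)
        table = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "c"])
        table["y"] = table[["a", "b", "c"]].sum(axis=1)
        res = standardized_regression(table, "y", ["a", "b", "c"])
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.see == pytest.approx(0.0, abs=1e-10)

    def test_betas_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(18)
        table = pd.DataFrame(rng.normal(size=(120, 2)), columns=["a", "b"])
        table["y"] = table.a - 0.5 * table.b + rng.normal(size=120)
        r1 = standardized_regression(table, "y", ["a", "b"])
        table["a"] = 100.0 * table["a"] + 7.0
        r2 = standardized_regression(table, "y", ["a", "b"])
        assert r2.standardized_betas["a"] == pytest.approx(
            r1.standardized_betas["a"], abs=1e-9)

    def test_collinear_predictors_rejected(self):
        rng = np.random.default_rng(19)
        table = pd.DataFrame({"a": rng.normal(size=30)})
        table["b"] = 3 * table.a
        table["y"] = rng.normal(size=30)
        with pytest.raises(StatsError, match="collinear"):
            standardized_regression(table, "y", ["a", "b"])

    def test_needs_enough_rows(self):
        table = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0], "y": [0.0, 1.0]})
        with pytest.raises(StatsError):
            standardized_regression(table, "y", ["a", "b"])
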