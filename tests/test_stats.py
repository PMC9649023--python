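import numpy as np
import pandas as pd
import pytest

from coldface import (StatsConfig, gate_and_compare_conditions,
                      gate_and_compare_paired, hedges_g_two_sample,
                      mauchly_test, mixed_anova, partial_eta_sq,
                      posthoc_pairwise, rm_anova_gg)
from coldface.stats import _hedges_j


def long_table(X, rng_groups=None):
    n, k = X.shape
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "within": np.tile([f"w{i}" for i in range(k)], n),
        "dv": X.ravel(),
    })
    if rng_groups is not None:
        df["between"] = np.repeat(rng_groups, k)
    return df


class TestTwoSampleGate:
    def test_identical_groups_zero_effect(self, rng):
        x = rng.normal(size=20)
        r = gate_and_compare_conditions(x, x.copy())
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.effect == pytest.approx(0.0, abs=1e-12)

    def test_welch_branch_fractional_df(self, rng):
        x = rng.normal(0, 1.0, 25)
        y = rng.normal(0, 6.0, 12)
        r = gate_and_compare_conditions(x, y)
        if r.test == "welch-t-test":
            # Welch-Satterthwaite closed form
            v1, v2 = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
            df = (v1 + v2) ** 2 / (v1 ** 2 / (x.size - 1) + v2 ** 2 / (y.size - 1))
            assert r.df == pytest.approx(df)
            assert r.df < x.size + y.size - 2
            assert not r.gates["equal_var"]

    def test_nonnormal_sample_takes_mannwhitney(self, rng):
        x = rng.lognormal(0, 1.5, 40) ** 2  # heavily skewed
        y = rng.normal(5, 1, 40)
        r = gate_and_compare_conditions(x, y)
        assert r.test == "mann-whitney-u"
        assert r.effect_name == "hedges_g"

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValueError):
            gate_and_compare_conditions([1.0, 2.0], rng.normal(size=10))


class TestPairedGate:
    def test_identical_pairs(self, rng):
        x = rng.normal(size=15)
        r = gate_and_compare_paired(x, x.copy())
        assert r.statistic == 0.0 and r.effect == 0.0 and r.p_raw == 1.0

    def test_constant_shift_detected(self, rng):
        x = rng.normal(0, 1, 15)
        r = gate_and_compare_paired(x + 2.0 + rng.normal(0, 0.5, 15), x)
        assert r.test == "paired-t-test" and r.p_raw < 0.001
        assert r.effect > 1.0

    def test_deterministic_shift_degenerate_case(self, rng):
        x = rng.normal(0, 1, 10)
        with pytest.warns(UserWarning):
            r = gate_and_compare_paired(x + 2.0, x)
        assert r.p_raw == 0.0 and np.isinf(r.statistic)

    def test_nonnormal_differences_take_wilcoxon(self, rng):
        x = rng.normal(size=40)
        y = x - rng.lognormal(0, 1.5, 40) ** 2
        r = gate_and_compare_paired(x, y)
        assert r.test == "wilcoxon"

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            gate_and_compare_paired(rng.normal(size=5), rng.normal(size=6))

    def test_wilcoxon_matches_enumeration_small_n(self):
        # exact two-sided p by enumerating all sign assignments, n = 7
        from itertools import product
        from scipy import stats as sps

        d = np.array([1.2, -0.4, 2.1, 0.9, -1.5, 0.3, 1.8])
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        stats_all = [sum(r for r, s in zip(ranks, signs) if s > 0)
                     for signs in product([-1, 1], repeat=7)]
        mu = np.mean(stats_all)
        p_exact = np.mean([abs(s - mu) >= abs(w_obs - mu) - 1e-12
                           for s in stats_all])
        res = sps.wilcoxon(d, alternative="two-sided", method="exact")
        assert res.pvalue == pytest.approx(p_exact, abs=1e-12)


class TestEffectSizes:
    def test_hedges_correction_factor(self, rng):
        # g differs from uncorrected d exactly by J(df), n=13/12
        x = rng.normal(1.0, 1.0, 13)
        y = rng.normal(0.0, 1.0, 12)
        from coldface.stats import cohens_d_two_sample
        d = cohens_d_two_sample(x, y)
        g, _ = hedges_g_two_sample(x, y)
        assert g == pytest.approx(d * _hedges_j(23))
        assert _hedges_j(23) == pytest.approx(1 - 3 / (4 * 23 - 1), abs=2e-3)

    def test_eta_zero_and_one_boundaries(self):
        assert partial_eta_sq(0.0, 5.0) == 0.0
        assert partial_eta_sq(5.0, 0.0) == 1.0

    def test_eta_ci_brackets_estimate(self, rng):
        X = rng.normal(size=(12, 3)) + np.array([0.0, 0.5, 1.0])
        r = rm_anova_gg(long_table(X))
        lo, hi = r.effect_ci
        assert 0.0 <= lo <= hi <= 1.0


class TestRmAnova:
    def test_two_levels_no_correction_possible(self, rng):
        X = rng.normal(size=(10, 2))
        r = rm_anova_gg(long_table(X))
        assert r.extra["eps"] == 1.0
        assert not r.gates["gg_applied"]

    def test_all_equal_responses_F_zero(self):
        X = np.tile(np.arange(8.0)[:, None], (1, 4))
        r = rm_anova_gg(long_table(X))
        assert r.statistic == pytest.approx(0.0, abs=1e-20)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        for _ in range(10):
            X = rng.normal(size=(int(rng.integers(6, 14)), int(rng.integers(3, 6))))
            df = long_table(X)
            mine = rm_anova_gg(df)
            ref = pg.rm_anova(data=df, dv="dv", within="within",
                              subject="subject", correction=True, detailed=True)
            assert mine.statistic == pytest.approx(ref.at[0, "F"], rel=1e-9)
            assert mine.extra["eps"] == pytest.approx(ref.at[0, "eps"], rel=1e-9)
            sp = pg.sphericity(df, dv="dv", within="within", subject="subject")
            W, chi2, dof, p = mauchly_test(
                df.pivot(index="subject", columns="within", values="dv"))
            assert W == pytest.approx(sp.W, rel=1e-9)
            assert p == pytest.approx(sp.pval, rel=1e-9, abs=1e-12)

    def test_missing_cells_rejected(self, rng):
        X = rng.normal(size=(6, 3))
        df = long_table(X).drop(index=3)
        with pytest.raises(ValueError):
            rm_anova_gg(df)


class TestMixedAnova:
    def test_group_labels_on_identical_data_interaction_zero(self):
        X = np.tile(np.array([1.0, 2.0, 3.0]), (10, 1))
        X += np.arange(10)[:, None]  # subject offsets only
        groups = np.array(["A"] * 5 + ["B"] * 5)
        res = mixed_anova(long_table(X, groups))
        assert res["interaction"].statistic == pytest.approx(0.0, abs=1e-18)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        for _ in range(10):
            n = int(rng.integers(5, 9)) * 2 + 1
            X = rng.normal(size=(n, int(rng.integers(3, 5))))
            groups = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
            df = long_table(X, groups)
            mine = mixed_anova(df)
            ref = pg.mixed_anova(data=df, dv="dv", within="within",
                                 subject="subject", between="between",
                                 correction=True)
            for i, key in enumerate(("between", "within", "interaction")):
                assert mine[key].statistic == pytest.approx(ref.at[i, "F"], rel=1e-9)
                assert mine[key].effect == pytest.approx(ref.at[i, "np2"], rel=1e-9)
            assert mine["within"].extra["eps"] == pytest.approx(
                ref.at[1, "eps"], rel=1e-9)

    def test_planted_interaction_detected(self, rng):
        # condition-specific slope over phases, large effect
        hits = 0
        for rep in range(40):
            n = 12
            subj = rng.normal(0, 1, 2 * n)[:, None]
            base = rng.normal(0, 1, (2 * n, 3))
            slope = np.array([0.0, 1.5, 3.0])
            X = base + subj
            X[n:] += slope  # group B drifts across phases
            groups = np.array(["A"] * n + ["B"] * n)
            res = mixed_anova(long_table(X, groups))
            hits += res["interaction"].p_raw < 0.05
        assert hits / 40 >= 0.9

    def test_single_group_rejected(self, rng):
        X = rng.normal(size=(6, 3))
        with pytest.raises(ValueError):
            mixed_anova(long_table(X, np.array(["A"] * 6)))


class TestPosthoc:
    def test_three_levels_three_comparisons(self, rng):
        X = rng.normal(size=(10, 3))
        results = posthoc_pairwise(long_table(X))
        assert len(results) == 3
        assert all(r.extra["n_comparisons"] == 3 for r in results)

    def test_bonferroni_cap_at_one(self, rng):
        X = rng.normal(size=(10, 3))
        for r in posthoc_pairwise(long_table(X)):
            assert r.p_adjusted == min(1.0, r.p_raw * 3)
            assert r.p_adjusted >= r.p_raw


def test_gated_pipeline_deterministic(rng):
    x, y = rng.normal(size=20), rng.normal(size=20)
    r1 = gate_and_compare_conditions(x, y)
    r2 = gate_and_compare_conditions(x, y)
    assert r1.as_dict() == r2.as_dict()
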