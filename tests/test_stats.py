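import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from lcgrad import phantom
from lcgrad.stats import (
    bh_fdr,
    bootstrap_group_comparison,
    calinski_harabasz,
    clusterability_vs_age,
    mann_whitney,
    manova_oneway,
    nested_f_test,
    partial_spearman,
    per_year_age_analysis,
    rank_transform,
    sliding_windows,
    window_behavior_analysis,
)


class TestRankTransform:
    def test_examples_and_tie_rule(self):
        np.testing.assert_allclose(rank_transform([10, 20, 30]), [1, 2, 3])
        np.testing.assert_allclose(rank_transform([5, 5, 7]), [1.5, 1.5, 3])

    def test_invariant_to_monotone_transform(self, rng):
        x = rng.standard_normal(25)
        np.testing.assert_allclose(rank_transform(x), rank_transform(np.exp(x)))


class TestPartialSpearman:
    def test_identity_without_covariates(self, rng):
        x = rng.standard_normal(15)
        rho, p = partial_spearman(x, x)
        assert rho == pytest.approx(1.0)
        assert p == 0.0

    def test_equals_plain_spearman(self, rng):
        x = rng.standard_normal(10)
        y = rng.standard_normal(10)
        rho, p = partial_spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_covariate_fully_explains(self, rng):
        c = rng.standard_normal(20)
        x = rng.standard_normal(20)
        rho, p = partial_spearman(x, c, c[:, None])
        assert abs(rho) < 1e-10
        assert p == 1.0

    def test_null_calibration(self):
        n_sig = 0
        for seed in range(400):
            r = np.random.default_rng(seed)
            x, y, c = r.standard_normal((3, 40))
            _, p = partial_spearman(x, y, c[:, None])
            n_sig += p < 0.05
        assert sps.binomtest(n_sig, 400, 0.05).pvalue > 0.05


class TestNestedFTest:
    def test_matches_bruteforce_rss(self, rng):
        n = 20
        Xn = rng.standard_normal((n, 2))
        add = rng.standard_normal((n, 3))
        y = rng.standard_normal(n)
        res = nested_f_test(y, Xn, np.column_stack([Xn, add]))

        def rss(X):
            X1 = np.column_stack([np.ones(n), X])
            b = np.linalg.solve(X1.T @ X1, X1.T @ y)
            r = y - X1 @ b
            return r @ r

        rss0, rss1 = rss(Xn), rss(np.column_stack([Xn, add]))
        F = ((rss0 - rss1) / 3) / (rss1 / (n - 5 - 1))
        assert res.F == pytest.approx(F, abs=1e-10)
        assert res.partial_r2 == pytest.approx((rss0 - rss1) / rss0, abs=1e-12)
        assert res.adj_partial_r2 <= res.partial_r2
        assert res.df == (3, 14)

    def test_textbook_simple_regression_equivalence(self):
        # y on x alone: nested F (intercept-only vs +x) equals t^2 of the slope
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 4, 5, 8, 9, 13])
        res = nested_f_test(y, None, x[:, None])
        lin = sps.linregress(x, y)
        t2 = (lin.slope / lin.stderr) ** 2
        assert res.F == pytest.approx(t2, rel=1e-10)
        assert res.p == pytest.approx(lin.pvalue, rel=1e-8)

    def test_perfect_fit_of_added_columns(self, rng):
        n = 15
        Xn = rng.standard_normal((n, 1))
        add = rng.standard_normal((n, 2))
        y = add @ np.array([1.0, -2.0])
        res = nested_f_test(y, Xn, np.column_stack([Xn, add]))
        assert res.partial_r2 == pytest.approx(1.0)
        assert res.F == np.inf and res.p == 0.0

    def test_null_mean_f_near_one_and_calibrated(self):
        Fs, n_sig = [], 0
        for seed in range(1000):
            r = np.random.default_rng(seed)
            n = 200
            Xn = r.standard_normal((n, 2))
            add = r.standard_normal((n, 3))
            y = r.standard_normal(n)
            res = nested_f_test(y, Xn, np.column_stack([Xn, add]))
            Fs.append(res.F)
            n_sig += res.p < 0.05
        assert np.mean(Fs) == pytest.approx(1.0, abs=0.1)
        assert sps.binomtest(n_sig, 1000, 0.05).pvalue > 0.05

    def test_rank_deficiency_reported(self, rng):
        n = 12
        Xn = rng.standard_normal((n, 1))
        dup = np.column_stack([Xn, Xn])  # duplicated column
        with pytest.raises(ValueError, match="collinear"):
            nested_f_test(rng.standard_normal(n), Xn, dup)


class TestSlidingWindows:
    @staticmethod
    def _series(n):
        return pd.Series(np.arange(n, dtype=float),
                         index=[f"s{i:04d}" for i in range(n)])

    def test_window_count_closed_form(self):
        # floor((n - window_length)/step) + 1 = floor((292-20)/5) + 1 = 55
        assert len(sliding_windows(self._series(292), 20, 5)) == 55

    def test_boundaries(self):
        assert len(sliding_windows(self._series(20), 20, 5)) == 1
        wins = sliding_windows(self._series(24), 20, 5)
        assert len(wins) == 1 and len(wins[0]) == 20  # 4 subjects dropped
        with pytest.raises(ValueError):
            sliding_windows(self._series(19), 20, 5)

    def test_sorted_by_score_with_deterministic_ties(self):
        s = pd.Series([3.0, 1.0, 2.0, 1.0], index=["d", "b", "a", "c"])
        wins = sliding_windows(s, 2, 1)
        assert wins[0] == ["b", "c"]  # ties broken by id
        assert wins[1] == ["c", "a"]
        assert wins[2] == ["a", "d"]


class TestCalinskiHarabasz:
    def test_matches_exhaustive_contiguous_split(self):
        v = np.array([0.0, 0.1, 1.0, 1.1])
        best = -np.inf
        for cut in range(1, 4):  # all contiguous 2-splits of sorted values
            a, b = v[:cut], v[cut:]
            grand = v.mean()
            B = a.size * (a.mean() - grand) ** 2 + b.size * (b.mean() - grand) ** 2
            W = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            best = max(best, (B / 1) / (W / 2))
        assert calinski_harabasz(v) == pytest.approx(best, rel=1e-12)

    def test_matches_sklearn_given_same_labels(self, rng):
        from sklearn.metrics import calinski_harabasz_score

        v = np.sort(rng.random(40))
        ours = calinski_harabasz(v)
        from lcgrad.stats import _kmeans_1d

        labels, _ = _kmeans_1d(v, 2)
        ref = calinski_harabasz_score(v[:, None], labels)
        assert ours == pytest.approx(ref, rel=1e-10)

    def test_sharper_transition_scores_higher(self):
        u = np.linspace(0, 1, 48)
        from scipy.special import expit

        linear = u
        sharp = expit(12 * (u - 0.5))
        assert calinski_harabasz(sharp) > calinski_harabasz(linear)

    def test_affine_invariance(self, rng):
        v = rng.random(30)
        assert calinski_harabasz(5.0 * v - 2.0) == pytest.approx(
            calinski_harabasz(v), rel=1e-9)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            calinski_harabasz(np.ones(10))


class TestBhFdr:
    def test_hand_computed_step_up(self):
        adj = bh_fdr([0.01, 0.02, 0.03, 0.5])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.5], atol=1e-12)

    def test_edge_cases(self):
        np.testing.assert_array_equal(bh_fdr([1.0, 1.0]), [1.0, 1.0])
        np.testing.assert_array_equal(bh_fdr([0.3]), [0.3])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(25)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_fdr(p), ref, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_bounds_and_order_preservation(self, pvals):
        p = np.array(pvals)
        adj = bh_fdr(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestMannWhitney:
    def test_exact_enumeration_example(self):
        U, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert U == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)  # 2/20 orderings

    def test_identical_samples_p_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_symmetry_under_swap(self, rng):
        a = rng.standard_normal(6)
        b = rng.standard_normal(5)
        _, p_ab = mann_whitney(a, b)
        _, p_ba = mann_whitney(b, a)
        assert p_ab == pytest.approx(p_ba, abs=1e-12)

    def test_exact_agrees_with_scipy_without_ties(self, rng):
        a = rng.standard_normal(7)
        b = rng.standard_normal(6)
        U, p = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert U == ref.statistic
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_sample_calibration(self):
        n_sig = 0
        for seed in range(400):
            r = np.random.default_rng(seed)
            _, p = mann_whitney(r.standard_normal(15), r.standard_normal(15))
            n_sig += p < 0.05
        assert sps.binomtest(n_sig, 400, 0.05).pvalue > 0.05


class TestManova:
    def test_matches_statsmodels_pillai(self, rng):
        from statsmodels.multivariate.manova import MANOVA

        g1 = rng.standard_normal((15, 3))
        g2 = rng.standard_normal((12, 3)) + 0.5
        res = manova_oneway([g1, g2])
        Y = np.vstack([g1, g2])
        group = np.r_[np.zeros(15), np.ones(12)]
        X = np.column_stack([np.ones(27), group])
        mv = MANOVA(Y, X)
        tab = mv.mv_test([("group", np.array([[0.0, 1.0]]))])
        stat = tab.results["group"]["stat"]
        assert res.pillai == pytest.approx(float(stat.loc["Pillai's trace", "Value"]),
                                           abs=1e-10)
        assert res.F == pytest.approx(float(stat.loc["Pillai's trace", "F Value"]),
                                      rel=1e-8)
        assert res.p == pytest.approx(float(stat.loc["Pillai's trace", "Pr > F"]),
                                      abs=1e-10)

    def test_two_group_sscp_bruteforce(self):
        g1 = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 3.0]])
        g2 = np.array([[4.0, 5.0], [5.0, 4.0], [6.0, 6.0]])
        res = manova_oneway([g1, g2])
        grand = np.vstack([g1, g2]).mean(axis=0)
        H = np.zeros((2, 2))
        E = np.zeros((2, 2))
        for g in (g1, g2):
            d = (g.mean(axis=0) - grand)[:, None]
            H += 3 * d @ d.T
            r = g - g.mean(axis=0)
            E += r.T @ r
        pillai = np.trace(np.linalg.inv(H + E) @ H)
        assert res.pillai == pytest.approx(pillai, abs=1e-10)

    def test_null_calibration(self):
        n_sig = 0
        for seed in range(400):
            r = np.random.default_rng(seed)
            res = manova_oneway([r.standard_normal((30, 5)),
                                 r.standard_normal((30, 5))])
            n_sig += res.p < 0.05
        assert sps.binomtest(n_sig, 400, 0.05).pvalue > 0.05

    def test_power_under_mean_shift(self):
        n_sig = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            res = manova_oneway([r.standard_normal((30, 5)),
                                 r.standard_normal((30, 5)) + 1.0])
            n_sig += res.p < 0.001
        assert n_sig >= 95

    def test_singular_sscp_rejected(self, rng):
        g = rng.standard_normal((10, 3))
        g[:, 2] = g[:, 0]  # collinear parameters
        with pytest.raises(ValueError, match="singular|parameter"):
            manova_oneway([g, g + 1.0])


class TestCohortAnalyses:
    """End-to-end checks on generated cohorts (kept small for speed)."""

    @pytest.fixture(scope="class")
    def effect_cohort(self):
        return phantom.simulate_cohort(200, seed=17)

    def test_window_behavior_detects_planted_coupling(self, effect_cohort):
        res = window_behavior_analysis(effect_cohort, "em_recognition")
        assert res.ftest.p < 0.05
        assert res.params.shape[1] == 18
        assert 0 <= res.ftest.adj_partial_r2 <= 1

    def test_window_behavior_row_order_invariant(self, effect_cohort):
        res1 = window_behavior_analysis(effect_cohort, "em_recognition")
        shuffled = phantom.Cohort(
            effect_cohort.table.sample(frac=1, random_state=1).reset_index(drop=True),
            list(effect_cohort.subjects.values()), effect_cohort.coords,
            effect_cohort.mask, effect_cohort.atlas, effect_cohort.parcel_labels,
            effect_cohort.config, effect_cohort.truth)
        res2 = window_behavior_analysis(shuffled, "em_recognition")
        assert res1.windows == res2.windows
        assert res1.ftest.F == pytest.approx(res2.ftest.F, rel=1e-12)

    def test_window_behavior_null_is_anticonservative(self):
        """Overlapping windows sorted by the outcome inflate the F-test under
        a score-independent null; the procedure does NOT control type-I at
        the window level (documented limitation of the windowed design)."""
        rej = 0
        for seed in range(8):
            coh = phantom.simulate_cohort(160, seed=100 + seed)
            res = window_behavior_analysis(coh, "hotel")  # pure-noise score
            rej += res.ftest.p < 0.05
        assert rej >= 2  # far above the nominal 5% would give ~0.4 expected

    def test_per_year_age_analysis_detects_planted_decline(self, effect_cohort):
        res = per_year_age_analysis(effect_cohort)
        assert res.ftest.p < 0.05
        coupled = res.table.set_index("parameter")
        assert (coupled.loc[["left_y", "right_y"], "p_fdr"] < 0.05).any()

    def test_single_subject_bins_equal_subject_tsm(self):
        coh = phantom.simulate_cohort(8, age_range=(20, 70), seed=3)
        res = per_year_age_analysis.__wrapped__ if False else None
        # bins with one subject: group gradient equals the subject's own
        sid = coh.ids[0]
        g_single = coh.group_gradient([sid])
        np.testing.assert_allclose(g_single.values, coh.gradient(sid).values,
                                   atol=1e-12)

    def test_clusterability_tracks_age(self, effect_cohort):
        res = clusterability_vs_age(effect_cohort)
        assert res.rho > 0
        assert res.p < 0.05

    def test_bootstrap_group_comparison_detects_planted_shift(self, effect_cohort):
        res = bootstrap_group_comparison(effect_cohort, iterations=60, seed=2)
        assert res.manova.p < 0.05
        assert (res.table["p_fdr"] >= res.table["p"] - 1e-15).all()

    def test_bootstrap_deterministic_under_seed(self, effect_cohort):
        r1 = bootstrap_group_comparison(effect_cohort, iterations=20, seed=9)
        r2 = bootstrap_group_comparison(effect_cohort, iterations=20, seed=9)
        np.testing.assert_array_equal(r1.group_params[0], r2.group_params[0])
        assert r1.manova.p == r2.manova.p

    def test_bootstrap_group_too_small_rejected(self):
        coh = phantom.simulate_cohort(25, seed=4)
        with pytest.raises(ValueError, match="draw"):
            bootstrap_group_comparison(coh, iterations=5, seed=0)
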