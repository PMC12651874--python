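"""Effect sizes, classical tests and exact Shapley attribution."""

import math
from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from copmech.datasets import load_cohort_demographics
from copmech.shapley import exact_shapley, shap_summary
from copmech.stats import (cohens_d, kruskal_wallis, magnitude_label,
                           one_way_anova, welch_t_test)


class TestCohensD:
    def test_identical_samples(self, rng):
        x = rng.standard_normal(10)
        e = cohens_d(x, x)
        assert e.d == 0.0 and e.magnitude == "negligible"

    def test_antisymmetry(self, rng):
        a, b = rng.standard_normal(8), rng.standard_normal(9) + 1
        assert cohens_d(a, b).d == pytest.approx(-cohens_d(b, a).d)

    def test_printed_bmi_summaries(self):
        """BMI of the two patient groups from the published cohort table:
        25.53 +- 1.37 vs 24.23 +- 5.65 (n = 6 each) gives d ~ 0.316.
        Hand arithmetic: s_p = sqrt((1.37^2 + 5.65^2)/2) = 4.111,
        d = 1.30 / 4.111."""
        df = load_cohort_demographics()
        ctrl = df[df.group == "pd_control"]["bmi"]
        tpei = df[df.group == "pd_tpei"]["bmi"]
        e = cohens_d(ctrl, tpei)
        assert e.d == pytest.approx(0.316, abs=0.001)
        assert e.magnitude == "small"

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(0.1, 50.0), shift=st.floats(-100.0, 100.0),
           seed=st.integers(0, 50))
    def test_affine_invariance(self, scale, shift, seed):
        r = np.random.default_rng(seed)
        a, b = r.standard_normal(12), r.standard_normal(12) + 0.5
        d0 = cohens_d(a, b).d
        d1 = cohens_d(scale * a + shift, scale * b + shift).d
        assert d1 == pytest.approx(d0, rel=1e-9)

    def test_magnitude_ladder(self):
        assert magnitude_label(0.1) == "negligible"
        assert magnitude_label(-0.66) == "medium"
        assert magnitude_label(1.0) == "large"
        assert magnitude_label(-1.5) == "very large"
        assert magnitude_label(12.1) == "huge"

    def test_zero_pooled_sd(self):
        with pytest.raises(ValueError, match="zero pooled SD"):
            cohens_d([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])


class TestWelch:
    def test_identical_samples(self):
        r = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_published_bmi_p_values(self):
        """Welch on the printed cohort rows reproduces the published
        demographic p-values 0.605 (control vs TPEI) and 0.547 (PD vs
        healthy)."""
        df = load_cohort_demographics()
        ctrl = df[df.group == "pd_control"]["bmi"]
        tpei = df[df.group == "pd_tpei"]["bmi"]
        healthy = df[df.group == "healthy"]["bmi"]
        pd_all = df[df.group != "healthy"]["bmi"]
        assert welch_t_test(ctrl, tpei).p_value == pytest.approx(0.605, abs=0.001)
        assert welch_t_test(pd_all, healthy).p_value == pytest.approx(0.547,
                                                                      abs=0.001)

    def test_agrees_with_exact_permutation_at_n4(self, rng):
        """Two-sided p within 0.02 of the exact two-sample permutation
        test at n1 = n2 = 4 (enumeration of all C(8,4) splits)."""
        a = np.array([-0.7, -1.3, -0.6, 0.0])
        b = np.array([-1.6, 0.5, -0.5, 0.0])
        welch_p = welch_t_test(a, b).p_value
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        count = 0
        total = 0
        for idx in combinations(range(8), 4):
            mask = np.zeros(8, bool)
            mask[list(idx)] = True
            diff = abs(pooled[mask].mean() - pooled[~mask].mean())
            count += diff >= obs - 1e-12
            total += 1
        assert welch_p == pytest.approx(count / total, abs=0.02)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(0)
        ps = [welch_t_test(rng.standard_normal(10),
                           rng.standard_normal(10)).p_value
              for _ in range(500)]
        from scipy.stats import kstest

        assert kstest(ps, "uniform").statistic < 0.1


class TestAnova:
    def test_equal_means_give_zero_f(self):
        r = one_way_anova([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_f_is_t_squared(self, rng):
        a, b = rng.standard_normal(8), rng.standard_normal(8) + 1
        from scipy.stats import ttest_ind

        t = ttest_ind(a, b, equal_var=True).statistic
        assert one_way_anova(a, b).statistic == pytest.approx(t**2, rel=1e-12)

    def test_hand_example_from_definition(self):
        """3 groups of 3 integers; F computed from raw sums of squares."""
        g = [np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]),
             np.array([7.0, 8.0, 9.0])]
        grand = np.mean(np.concatenate(g))
        ssb = sum(3 * (x.mean() - grand) ** 2 for x in g)
        ssw = sum(((x - x.mean()) ** 2).sum() for x in g)
        f_oracle = (ssb / 2) / (ssw / 6)
        r = one_way_anova(*g)
        assert r.statistic == pytest.approx(f_oracle, rel=1e-12)
        assert r.df == (2.0, 6.0)


class TestKruskal:
    def test_identical_rank_distributions(self):
        r = kruskal_wallis([1.0, 5.0, 9.0], [2.0, 6.0, 10.0], [3.0, 7.0, 11.0])
        assert r.statistic < 1.0  # near-identical rank sums

    def test_all_identical_values_convention(self):
        r = kruskal_wallis([2.0, 2.0], [2.0, 2.0])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_monotone_transform_invariance(self, rng):
        a, b = rng.standard_normal(7), rng.standard_normal(6) + 0.5
        base = kruskal_wallis(a, b)
        warped = kruskal_wallis(np.exp(a), np.exp(b))
        assert warped.statistic == pytest.approx(base.statistic, rel=1e-12)

    def test_small_example_vs_exact_permutation(self):
        """H's chi-square p compared with exact enumeration of group
        assignments (2 groups of 3, no ties). At n = 3+3 the chi-square
        approximation is known to be crude (exact enumeration has
        granularity 1/20 and the asymptotic p can be ~0.13 off); the
        assertion bounds that approximation error."""
        a = np.array([1.0, 3.0, 5.0])
        b = np.array([2.0, 9.0, 11.0])
        r = kruskal_wallis(a, b)
        pooled = np.concatenate([a, b])
        obs = r.statistic
        count = total = 0
        for idx in combinations(range(6), 3):
            mask = np.zeros(6, bool)
            mask[list(idx)] = True
            h = kruskal_wallis(pooled[mask], pooled[~mask]).statistic
            count += h >= obs - 1e-12
            total += 1
        assert count / total == pytest.approx(0.4)  # exact enumeration value
        assert r.p_value == pytest.approx(count / total, abs=0.15)


class TestExactShapley:
    def test_linear_model_closed_form(self, rng):
        w = np.array([2.0, -1.0, 0.5, 3.0])
        bg = rng.standard_normal((40, 4))
        x = rng.standard_normal(4)
        rep = exact_shapley(lambda A: A @ w, x, bg)
        np.testing.assert_allclose(rep.phi, w * (x - bg.mean(axis=0)),
                                   atol=1e-12)

    def test_null_player_gets_zero(self, rng):
        bg = rng.standard_normal((20, 3))
        rep = exact_shapley(lambda A: A[:, 0] ** 2, np.ones(3), bg)
        assert rep.phi[1] == 0.0 and rep.phi[2] == 0.0

    def test_symmetric_features_get_equal_phi(self, rng):
        bg = rng.standard_normal((20, 1))
        bg = np.hstack([bg, bg])  # duplicated feature columns
        rep = exact_shapley(lambda A: A[:, 0] + A[:, 1], np.array([2.0, 2.0]),
                            bg)
        assert rep.phi[0] == pytest.approx(rep.phi[1], abs=1e-12)

    def test_matches_permutation_average_oracle(self, rng):
        """phi from coalition enumeration equals the average marginal
        contribution over all d! feature orderings."""
        d = 4
        rng_w = np.random.default_rng(7)
        M = rng_w.standard_normal((d, d))
        f = lambda A: np.sin(A @ M[:, 0]) + (A @ M[:, 1]) ** 2  # noqa: E731
        bg = rng.standard_normal((15, d))
        x = rng.standard_normal(d)
        rep = exact_shapley(f, x, bg)

        def v(S):
            comp = np.tile(bg, (1, 1))
            comp = bg.copy()
            for i in S:
                comp[:, i] = x[i]
            return f(comp).mean()

        phi_oracle = np.zeros(d)
        for order in permutations(range(d)):
            S = []
            for i in order:
                phi_oracle[i] += v(S + [i]) - v(S)
                S.append(i)
        phi_oracle /= math.factorial(d)
        np.testing.assert_allclose(rep.phi, phi_oracle, atol=1e-10)

    def test_additivity_asserted(self, rng):
        bg = rng.standard_normal((10, 3))
        x = rng.standard_normal(3)
        rep = exact_shapley(lambda A: np.tanh(A).sum(axis=1), x, bg)
        assert rep.phi.sum() == pytest.approx(rep.prediction - rep.base_value,
                                              abs=1e-9)

    def test_too_many_features_rejected(self, rng):
        with pytest.raises(ValueError, match="at most"):
            exact_shapley(lambda A: A.sum(axis=1), np.zeros(13),
                          rng.standard_normal((5, 13)))


class TestShapSummary:
    def test_single_instance_ranking_is_abs_phi(self, rng):
        bg = rng.standard_normal((10, 2))
        rep = exact_shapley(lambda A: A @ np.array([3.0, -1.0]),
                            np.array([1.0, 1.0]), bg, ["big", "small"])
        ranking, dep = shap_summary([rep])
        assert list(ranking["feature"]) == ["big", "small"]
        np.testing.assert_allclose(sorted(ranking["mean_abs_phi"], reverse=True),
                                   sorted(np.abs(rep.phi), reverse=True))

    def test_duplicated_instances_duplicate_dependence_pairs(self, rng):
        bg = rng.standard_normal((10, 2))
        rep = exact_shapley(lambda A: A.sum(axis=1), np.ones(2), bg)
        _, dep = shap_summary([rep, rep])
        first = dep[dep.feature == "x0"]
        assert len(first) == 2
        assert first["phi"].nunique() == 1

    def test_inconsistent_feature_sets_rejected(self, rng):
        bg = rng.standard_normal((5, 2))
        a = exact_shapley(lambda A: A.sum(axis=1), np.ones(2), bg, ["a", "b"])
        b = exact_shapley(lambda A: A.sum(axis=1), np.ones(2), bg, ["a", "c"])
        with pytest.raises(ValueError, match="inconsistent"):
            shap_summary([a, b])
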