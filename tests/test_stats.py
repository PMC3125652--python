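"""Inferential toolkit vs hand computations, enumeration and scipy oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from basalmorph.stats import (
    DegenerateDataError,
    kruskal_wallis,
    mann_whitney,
    one_way_anova,
    run_full_comparison,
    t_test_pooled,
)
from basalmorph.morphometry import InsufficientDataError
from basalmorph.synthesis import default_spec, generate_tabular


class TestOneWayAnova:
    def test_textbook_three_groups(self):
        a = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert a.between_ss == pytest.approx(6.0)
        assert a.within_ss == pytest.approx(6.0)
        assert (a.df_between, a.df_within) == (2, 6)
        assert a.f_ratio == pytest.approx(3.0)

    def test_equal_means_give_zero_f(self):
        a = one_way_anova([[1, 2, 3], [0, 2, 4], [2, 2, 2.0001]])
        assert a.f_ratio == pytest.approx(0.0, abs=1e-6)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(loc, 1.0, size=n) for loc, n in ((0, 8), (0.5, 12), (1, 9))]
        a = one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert a.f_ratio == pytest.approx(ref.statistic, rel=1e-10)
        assert a.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_degenerate_within_variance(self):
        with pytest.raises(DegenerateDataError):
            one_way_anova([[1.0, 1.0], [2.0, 2.0]])

    def test_too_few_groups(self):
        with pytest.raises(InsufficientDataError):
            one_way_anova([[1, 2, 3]])

    @given(
        data=st.lists(
            st.lists(st.floats(-100, 100), min_size=2, max_size=8),
            min_size=2,
            max_size=5,
        )
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_ss_conservation_on_random_inputs(self, data):
        arrs = [np.asarray(g) for g in data]
        if sum(((a - a.mean()) ** 2).sum() for a in arrs) <= 1e-12:
            return
        a = one_way_anova(arrs)
        assert a.between_ss + a.within_ss == pytest.approx(a.total_ss, rel=1e-9, abs=1e-9)
        assert a.df_between + a.df_within == a.df_total
        assert a.between_ss >= -1e-12 and a.within_ss >= 0

    def test_two_group_anova_equals_squared_pooled_t(self, rng):
        x, y = rng.normal(0, 1, 14), rng.normal(0.8, 1, 9)
        a = one_way_anova([x, y])
        t = t_test_pooled(x, y)
        assert a.f_ratio == pytest.approx(t.statistic**2, rel=1e-10)
        assert a.p_value == pytest.approx(t.p_value, rel=1e-9)


class TestPooledT:
    def test_hand_computed(self):
        r = t_test_pooled([1, 2, 3], [4, 5, 6])
        assert r.statistic == pytest.approx(3.0 / math.sqrt(2.0 / 3.0), rel=1e-12)
        assert r.df == 4

    def test_identical_samples_zero(self):
        r = t_test_pooled([1, 2, 3], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0)

    def test_matches_scipy_equal_var(self, rng):
        x, y = rng.normal(0, 2, 30), rng.normal(1, 2, 10)
        r = t_test_pooled(x, y)
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert r.statistic == pytest.approx(abs(ref.statistic), rel=1e-10)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-10)
        assert r.df == 38

    def test_zero_pooled_variance(self):
        with pytest.raises(DegenerateDataError):
            t_test_pooled([2.0, 2.0], [2.0, 2.0])


def exact_u_moments(n1, n2):
    """Enumerate the exact null distribution of U (no ties)."""
    ranks = range(1, n1 + n2 + 1)
    us = [
        sum(c) - n1 * (n1 + 1) / 2 for c in itertools.combinations(ranks, n1)
    ]
    return float(np.mean(us)), float(np.var(us))


class TestMannWhitney:
    def test_complete_separation_10_vs_30(self):
        a = list(range(10))
        b = list(range(100, 130))
        r = mann_whitney(a, b)
        assert r.details["U"] == 0.0
        assert r.statistic == pytest.approx(150.0 / math.sqrt(1025.0), rel=1e-12)

    def test_small_separation_brute_force(self):
        r = mann_whitney([1, 2, 3], [4, 5])
        assert r.details["U"] == 0.0
        assert r.statistic == pytest.approx(3.0 / math.sqrt(3.0), rel=1e-12)

    def test_identical_samples_symmetric(self):
        a = [1.0, 5.0, 9.0, 12.0]
        r = mann_whitney(a, a)
        assert r.details["U"] == pytest.approx(len(a) ** 2 / 2)
        assert r.statistic == pytest.approx(0.0)

    @pytest.mark.parametrize("n1,n2", [(3, 4), (5, 5), (4, 8), (6, 6)])
    def test_normal_approximation_matches_exact_moments(self, n1, n2):
        """For total n ≤ 12 the approximation's μ and σ² equal the moments of
        the exhaustively enumerated exact null distribution of U."""
        mu, var = exact_u_moments(n1, n2)
        x = list(range(n1))  # complete separation → U = 0, no ties
        y = list(range(100, 100 + n2))
        r = mann_whitney(x, y)
        assert r.details["U"] == 0.0
        assert n1 * n2 / 2.0 == pytest.approx(mu, rel=1e-12)
        sigma_used = (r.details["U"] - n1 * n2 / 2.0) / r.details["z_signed"]
        assert sigma_used**2 == pytest.approx(var, rel=1e-9)

    def test_matches_scipy_asymptotic_no_continuity(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.7, 1, 15)
        r = mann_whitney(x, y)
        ref = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert r.details["U"] == pytest.approx(ref.statistic)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_tie_correction_against_scipy(self):
        x = [1, 2, 2, 3, 5, 5, 5]
        y = [2, 3, 3, 5, 6]
        r = mann_whitney(x, y)
        ref = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_continuity_flag(self):
        r0 = mann_whitney([1, 2, 3], [4, 5], continuity=False)
        r1 = mann_whitney([1, 2, 3], [4, 5], continuity=True)
        assert r1.statistic < r0.statistic

    def test_all_tied_degenerate(self):
        with pytest.raises(DegenerateDataError):
            mann_whitney([3.0, 3.0], [3.0, 3.0, 3.0])


class TestKruskalWallis:
    def test_hand_computed_no_ties(self):
        r = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert r.statistic == pytest.approx(32.0 / 7.0, rel=1e-12)
        assert r.df == 2

    def test_matches_scipy_with_ties(self, rng):
        groups = [[1, 2, 2, 5], [2, 3, 3], [4, 4, 6, 7, 7]]
        r = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert r.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_all_identical_degenerate(self):
        with pytest.raises(DegenerateDataError):
            kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])


@pytest.mark.parametrize(
    "transform",
    [lambda x: 3.0 * x + 2.0, np.exp, lambda x: x**3],
    ids=["affine", "exp", "cube"],
)
def test_rank_tests_invariant_under_monotone_transforms(transform, rng):
    x = rng.normal(0, 1, 15)
    y = rng.normal(0.5, 1.3, 11)
    z = rng.normal(1.0, 0.8, 13)
    base_mw = mann_whitney(x, y)
    base_kw = kruskal_wallis([x, y, z])
    t_mw = mann_whitney(transform(x), transform(y))
    t_kw = kruskal_wallis([transform(x), transform(y), transform(z)])
    assert t_mw.statistic == pytest.approx(base_mw.statistic, rel=1e-10)
    assert t_kw.statistic == pytest.approx(base_kw.statistic, rel=1e-10)


def test_form_pe_and_ci_give_identical_rank_results(cohort_values):
    """CI is a strictly decreasing transform of form PE per compartment, so
    every pairwise rank test agrees between the two descriptors."""
    for compartment in ("nuclear", "cellular"):
        for a, b in (("normal", "leukoplakia"), ("normal", "scc"), ("leukoplakia", "scc")):
            z_fpe = mann_whitney(
                cohort_values(a, f"{compartment}_form_pe"),
                cohort_values(b, f"{compartment}_form_pe"),
            ).statistic
            z_ci = mann_whitney(
                cohort_values(a, f"{compartment}_ci"),
                cohort_values(b, f"{compartment}_ci"),
            ).statistic
            assert z_ci == pytest.approx(z_fpe, rel=1e-10)


class TestNullCalibration:
    def test_type_i_error_near_nominal(self):
        """Permutation-free null simulation: with all three groups drawn from
        one distribution, each test rejects at ≈ the nominal 5% level."""
        rng = np.random.default_rng(1234)
        n_sim = 2000
        rej = {"anova": 0, "kw": 0, "mw": 0, "t": 0}
        for _ in range(n_sim):
            g = [rng.normal(0, 1, 10), rng.normal(0, 1, 12), rng.normal(0, 1, 10)]
            if one_way_anova(g).p_value <= 0.05:
                rej["anova"] += 1
            if kruskal_wallis(g).p_value <= 0.05:
                rej["kw"] += 1
            if mann_whitney(g[0], g[1]).p_value <= 0.05:
                rej["mw"] += 1
            if t_test_pooled(g[0], g[1]).p_value <= 0.05:
                rej["t"] += 1
        # 3.3σ Monte-Carlo band around 0.05 at n_sim = 2000 → ±0.016
        for name, k in rej.items():
            assert 0.034 <= k / n_sim <= 0.066, (name, k / n_sim)


class TestFullComparison:
    def test_missing_group_is_configuration_error(self, cohort):
        from basalmorph.stats import ConfigurationError

        subset = [r for r in cohort if r.group != "scc"]
        with pytest.raises(ConfigurationError, match="scc"):
            run_full_comparison(subset)

    def test_report_is_complete(self, cohort):
        rep = run_full_comparison(cohort)
        assert set(rep.anova) == {
            "nuclear_area",
            "cell_area",
            "nuclear_form_pe",
            "cellular_form_pe",
            "nuclear_ci",
            "cellular_ci",
            "nc_ratio",
        }
        for v, ts in rep.t_tests.items():
            assert len(ts) == 3 and all(t.df in (38, 58) for t in ts)
        assert len(rep.summaries) == 9 * 3

    def test_synthetic_cohort_recovers_group_effects(self):
        """Statistics on a generated tabular cohort: the generator's size
        gradient is detected as significant group effects."""
        records = generate_tabular(default_spec(seed=42))
        rep = run_full_comparison(records)
        assert rep.anova["nuclear_area"].p_value <= 0.05
        assert rep.anova["cell_area"].p_value <= 0.05
        for t in rep.t_tests["nuclear_area"]:
            assert t.p_value <= 0.05

    def test_circle_constant_does_not_change_any_statistic(self, cohort):
        from basalmorph.morphometry import CIRCLE_22_7

        a = run_full_comparison(cohort)
        b = run_full_comparison(cohort, circle_constant=CIRCLE_22_7)
        for v in a.anova:
            if "form_pe" in v or v in ("nuclear_ci", "cellular_ci", "nc_ratio"):
                assert b.anova[v].f_ratio == pytest.approx(a.anova[v].f_ratio, rel=1e-9)
                for ta, tb in zip(a.mann_whitney[v], b.mann_whitney[v]):
                    assert tb.statistic == pytest.approx(ta.statistic, rel=1e-9)
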