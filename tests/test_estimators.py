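"""Statistical core: ratio estimator, ANOVA ICC, DEFF, sample size."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from clustericc.cohort import ClusterSummary, VariableSpec, Rule
from clustericc.estimators import (
    FLAG_CONSTANT,
    FLAG_DEFF_UNDEFINED,
    FLAG_MSW_ZERO,
    anova_icc,
    design_effect,
    estimate_variable,
    ratio_estimator,
    recalc_sample_size,
)
from clustericc.simulate import (
    STUDY_CLUSTER_SIZES,
    SimulationScenario,
    generate_cohort,
    sample_cluster_values,
)

from conftest import naive_anova_icc, naive_design_effect


class TestRatioEstimator:
    def test_is_the_pooled_proportion(self):
        summaries = [ClusterSummary("A", 2, 2), ClusterSummary("B", 1, 0)]
        assert ratio_estimator(summaries) == pytest.approx(2 / 3)

    def test_boundary_all_successes(self):
        summaries = [ClusterSummary("A", 4, 4), ClusterSummary("B", 2, 2)]
        assert ratio_estimator(summaries) == 1.0

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            ratio_estimator([])

    def test_within_monte_carlo_error_of_truth(self):
        # independent sampling: pooled proportion ~ Binomial(n, 0.5)/n
        rng = np.random.default_rng(7)
        n = 9555
        values = rng.binomial(1, 0.5, size=n)
        bounds = np.cumsum([0] + list(STUDY_CLUSTER_SIZES))
        summaries = [
            ClusterSummary(str(i), int(hi - lo), int(values[lo:hi].sum()))
            for i, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:]))
        ]
        se = math.sqrt(0.25 / n)
        assert abs(ratio_estimator(summaries) - 0.5) < 3 * se


class TestAnovaIcc:
    def test_toy_case_matches_hand_anova(self, toy_groups):
        est = anova_icc(toy_groups)
        assert est.F == pytest.approx(7.0)
        assert est.msb == pytest.approx(7 / 9)
        assert est.msw == pytest.approx(1 / 9)
        assert est.rho == pytest.approx(2 / 3)
        assert est.ci_low <= est.rho_reported <= est.ci_high

    def test_f_agrees_with_scipy(self, toy_groups):
        f_ref = stats.f_oneway(*toy_groups).statistic
        assert anova_icc(toy_groups).F == pytest.approx(f_ref)

    def test_perfect_within_cluster_homogeneity_is_degenerate(self):
        est = anova_icc([[1, 1], [0, 0]])
        assert est.rho == 1.0
        assert math.isinf(est.F)
        assert FLAG_MSW_ZERO in est.flags

    def test_zero_between_cluster_variance_clamps_to_zero(self):
        est = anova_icc([[1, 0], [1, 0]])
        assert est.rho == pytest.approx(-1.0)
        assert est.rho_reported == 0.0
        assert est.display == "<0.001"

    def test_all_identical_values_flagged(self):
        est = anova_icc([[1, 1], [1, 1]])
        assert est.rho == 0.0
        assert FLAG_CONSTANT in est.flags

    @pytest.mark.parametrize(
        "groups, err",
        [
            ([[1, 0]], "2 clusters"),
            ([[1], []], "at least one observation"),
            ([[1], [0]], "n > a"),
        ],
    )
    def test_invalid_inputs(self, groups, err):
        with pytest.raises(ValueError, match=err):
            anova_icc(groups)

    @given(
        b=st.integers(min_value=2, max_value=6),
        a=st.integers(min_value=2, max_value=5),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_f_form_equals_variance_components_form_for_equal_sizes(self, b, a, seed):
        rng = np.random.default_rng(seed)
        groups = rng.binomial(1, 0.5, size=(a, b)).tolist()
        est = anova_icc(groups)
        if est.flags:
            return
        k = b
        ms_form = (est.msb - est.msw) / (est.msb + (k - 1) * est.msw)
        assert est.rho == pytest.approx(ms_form, abs=1e-12)

    def test_se_matches_swiger_closed_form_for_equal_sizes(self):
        # Swiger et al. equal-size variance is the special case of Smith's
        rng = np.random.default_rng(3)
        a, b = 10, 8
        groups = rng.binomial(1, 0.4, size=(a, b)).tolist()
        est = anova_icc(groups)
        n = a * b
        var = (
            2 * (n - 1) * (1 - est.rho) ** 2 * (1 + (b - 1) * est.rho) ** 2
            / (b**2 * (n - b) * (a - 1))
        )
        # Smith's formula has (a-1)(1-rho)(1+(2k-1)rho)/(a-1)^2 + ... which
        # reduces to the same order; both are asymptotic, agree closely
        assert est.se == pytest.approx(math.sqrt(var), rel=0.15)

    def test_ci_clamped_to_unit_interval(self):
        est = anova_icc([[1, 0, 0], [0, 0, 1], [1, 0, 1]])
        assert 0.0 <= est.ci_low <= est.ci_high <= 1.0


class TestDesignEffect:
    def test_toy_case_from_definitions(self, toy_summaries):
        est = design_effect(toy_summaries)
        assert est.var_actual == pytest.approx(42 / 486)
        assert est.var_srs == pytest.approx(20 / 648)
        assert est.deff == pytest.approx(2.8)

    def test_equal_cluster_ratios_give_zero(self):
        summaries = [ClusterSummary("A", 4, 2), ClusterSummary("B", 2, 1)]
        assert design_effect(summaries).deff == 0.0

    def test_boundary_prevalence_flagged_undefined(self):
        summaries = [ClusterSummary("A", 3, 0), ClusterSummary("B", 3, 0)]
        est = design_effect(summaries)
        assert math.isnan(est.deff)
        assert FLAG_DEFF_UNDEFINED in est.flags

    def test_invariant_to_cluster_relabeling(self, toy_summaries):
        relabeled = [
            ClusterSummary(s.cluster_id[::-1] + "x", s.x, s.y) for s in reversed(toy_summaries)
        ]
        assert design_effect(relabeled).deff == pytest.approx(
            design_effect(toy_summaries).deff
        )

    @given(scale=st.integers(min_value=1, max_value=9))
    @settings(max_examples=9, deadline=None, derandomize=True)
    def test_scaling_counts_leaves_prevalence_unchanged(self, scale):
        summaries = [ClusterSummary("A", 3, 1), ClusterSummary("B", 5, 4)]
        scaled = [ClusterSummary(s.cluster_id, s.x * scale, s.y * scale) for s in summaries]
        assert ratio_estimator(scaled) == pytest.approx(ratio_estimator(summaries))

    def test_matches_classical_identity_for_equal_clusters(self):
        # equal clusters of size b at ICC rho: E[DEFF] ~= 1 + (b-1) rho
        rho, b, a = 0.3, 50, 40
        reps, deffs = 200, []
        rng = np.random.default_rng(11)
        for _ in range(reps):
            sc = SimulationScenario(
                mu=0.5, rho=rho, cluster_sizes=(b,) * a,
                seed=int(rng.integers(2**31)),
            )
            values = sample_cluster_values(sc)
            summaries = [
                ClusterSummary(str(i), v.size, int(np.nansum(v)))
                for i, v in enumerate(values)
            ]
            deffs.append(design_effect(summaries).deff)
        expected = 1 + (b - 1) * rho
        se = np.std(deffs, ddof=1) / math.sqrt(reps)
        assert abs(np.mean(deffs) - expected) < 4 * se + 0.05 * expected


class TestOracleEquivalence:
    def test_random_small_instances_match_definitions(self):
        # dual route: vectorized implementation vs plain-loop definitions
        rng = np.random.default_rng(2027)
        checked = 0
        for _ in range(300):
            a = int(rng.integers(2, 6))
            sizes = rng.integers(1, 7, size=a)
            if sizes.sum() <= a:
                continue
            groups = [rng.binomial(1, rng.uniform(0.2, 0.8), size=s).tolist() for s in sizes]
            est = anova_icc(groups)
            pairs = [(len(g), sum(g)) for g in groups]
            r = sum(y for _, y in pairs) / sum(x for x, _ in pairs)
            if est.flags or r in (0.0, 1.0):
                continue
            f_ref, rho_ref = naive_anova_icc(groups)
            assert est.F == pytest.approx(f_ref, abs=1e-12)
            assert est.rho == pytest.approx(rho_ref, abs=1e-12)
            summaries = [ClusterSummary(str(i), x, y) for i, (x, y) in enumerate(pairs)]
            assert design_effect(summaries).deff == pytest.approx(
                naive_design_effect(pairs), abs=1e-12
            )
            checked += 1
        assert checked > 150


class TestRecalcSampleSize:
    def test_study_headline_value(self):
        res = recalc_sample_size(a=27, icc=0.077, deff=21.09)
        assert res.n_star == 7072

    def test_deff_one_reduces_to_cluster_count(self):
        assert recalc_sample_size(a=27, icc=0.077, deff=1.0).n_star == 27

    def test_direct_evaluation(self):
        assert recalc_sample_size(a=27, icc=0.5, deff=2.0).n_star == 81

    def test_non_positive_icc_is_an_error(self):
        with pytest.raises(ValueError, match="non-positive ICC"):
            recalc_sample_size(a=27, icc=0.0, deff=2.0)

    def test_n_star_at_least_a_when_deff_geq_one(self):
        for icc in (0.01, 0.1, 0.9):
            for deff in (1.0, 1.5, 30.0):
                assert recalc_sample_size(a=27, icc=icc, deff=deff).n_star >= 27


class TestEstimateVariable:
    def test_full_denominator_mean_cluster_size(self):
        sc = SimulationScenario(mu=0.3, rho=0.05, seed=5)
        cohort = generate_cohort(sc, variable="v")
        spec = VariableSpec(name="v", block="outcome", success=Rule("equals", "1"))
        res = estimate_variable(cohort, spec)
        assert res.n_a == 354
        assert res.a_eff == 27
        assert 0 <= res.p_percent <= 100

    def test_propagates_missingness_into_n_a(self):
        sc = SimulationScenario(mu=0.3, rho=0.05, missing_rate=0.5, seed=5)
        cohort = generate_cohort(sc, variable="v")
        spec = VariableSpec(name="v", block="outcome", success=Rule("equals", "1"))
        res = estimate_variable(cohort, spec)
        assert res.valid_n < 9555
        assert res.n_a == round(res.valid_n / res.a_eff)

    def test_independent_variable_reports_near_zero_icc(self):
        # under rho = 0 the estimated ICC should essentially never reach 0.05
        rng = np.random.default_rng(29)
        hits = 0
        reps = 100
        for _ in range(reps):
            sc = SimulationScenario(mu=0.25, rho=0.0, seed=int(rng.integers(2**31)))
            est = anova_icc(sample_cluster_values(sc))
            if est.rho_reported < 0.05:
                hits += 1
        assert hits >= 0.9 * reps
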