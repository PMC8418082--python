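import numpy as np
import pytest
from statsmodels.stats.proportion import proportion_confint

from seizeval.cluster_stats import (
    BootstrapConfig,
    clustered_diff_test,
    cluster_summary,
    corrected_sensitivity,
    far_bootstrap_ci,
    far_normal_ci,
    far_ratio_test,
    icc_anova,
    laplace_estimate,
    min_clusters_for_sensitivity,
    precision_estimate,
    wilson,
    wilson_halfwidth,
)
from seizeval.core import ClusterOutcome, UndefinedResultError


def singletons(n, x, prefix="c"):
    return [ClusterOutcome(f"{prefix}{i}", 1, 1 if i < x else 0) for i in range(n)]


@pytest.mark.parametrize("x,n", [(0, 10), (3, 7), (34, 35), (65, 66), (50, 100)])
def test_wilson_bounds_match_statsmodels(x, n):
    lo, hi = proportion_confint(x, n, alpha=0.05, method="wilson")
    est = wilson(x, n)
    assert est.lower == pytest.approx(lo, abs=1e-10)
    assert est.upper == pytest.approx(hi, abs=1e-10)


def test_wilson_contains_midpoint_and_mle():
    rng = np.random.default_rng(2)
    for _ in range(100):
        n = int(rng.integers(1, 200))
        x = int(rng.integers(0, n + 1))
        est = wilson(x, n)
        assert est.lower <= est.estimate <= est.upper
        assert est.lower - 1e-12 <= x / n <= est.upper + 1e-12


def test_wilson_zero_successes_lower_edge():
    assert wilson(0, 10).lower == pytest.approx(0.0, abs=1e-3)
    with pytest.raises(UndefinedResultError):
        wilson(0, 0)


def test_wilson_width_shrinks_with_n():
    assert wilson_halfwidth(800, 1000) < wilson_halfwidth(80, 100) < wilson_halfwidth(8, 10)


def test_icc_degenerate_cases():
    assert icc_anova(singletons(10, 4)) == 0.0
    homogeneous = [ClusterOutcome("a", 3, 3), ClusterOutcome("b", 3, 0)]
    assert icc_anova(homogeneous) == 1.0
    with pytest.raises(UndefinedResultError):
        icc_anova([])


def test_icc_recovers_beta_binomial_truth():
    rng = np.random.default_rng(42)
    true_icc = 0.3
    s = 1 / true_icc - 1
    outs = []
    for i in range(50):
        m = int(rng.integers(2, 6))
        p = rng.beta(0.7 * s, 0.3 * s)
        outs.append(ClusterOutcome(f"c{i}", m, int(rng.binomial(m, p))))
    assert icc_anova(outs) == pytest.approx(true_icc, abs=0.15)


def test_corrected_sensitivity_reduces_to_wilson_for_singletons():
    a = corrected_sensitivity(singletons(35, 34))
    b = wilson(34, 35)
    assert (a.estimate, a.lower, a.upper) == (b.estimate, b.lower, b.upper)


def test_all_detected_forces_unit_design_effect():
    clustered = [ClusterOutcome("a", 4, 4), ClusterOutcome("b", 2, 2), ClusterOutcome("c", 1, 1)]
    summ = cluster_summary(clustered)
    assert summ.design_effect == 1.0
    assert corrected_sensitivity(clustered).estimate == wilson(7, 7).estimate


def test_clustering_widens_the_interval():
    rng = np.random.default_rng(7)
    s = 1 / 0.4 - 1
    outs = []
    for i in range(20):
        m = int(rng.integers(1, 6))
        p = rng.beta(0.8 * s, 0.2 * s)
        outs.append(ClusterOutcome(f"c{i}", m, int(rng.binomial(m, p))))
    summ = cluster_summary(outs)
    assert summ.design_effect > 1.0
    corrected = corrected_sensitivity(outs)
    naive = wilson(summ.n_detected, summ.n_events)
    assert corrected.upper - corrected.lower >= naive.upper - naive.lower


def test_laplace_estimate_properties():
    values = [laplace_estimate(x) for x in range(0, 60)]
    assert all(v < 1 for v in values)
    assert all(b > a for a, b in zip(values, values[1:]))


def test_precision_point_estimate_is_mle_with_wilson_bounds():
    est = precision_estimate(65, 357)
    assert est.estimate == pytest.approx(65 / 422)
    lo, hi = proportion_confint(65, 422, method="wilson")
    assert est.lower == pytest.approx(lo, abs=1e-10)
    with pytest.raises(UndefinedResultError):
        precision_estimate(0, 0)


def test_precision_laplace_when_no_false_alarms():
    est = precision_estimate(19, 0)
    assert est.method.value == "laplace"
    assert est.estimate == pytest.approx(20 / 21)
    assert est.lower < est.estimate <= est.upper


def test_bootstrap_degenerate_cases():
    single = far_bootstrap_ci([(2, 48.0)], BootstrapConfig(n_iterations=1000, seed=0))
    assert single.estimate == pytest.approx(1.0)
    assert (single.lower, single.upper) == (single.estimate, single.estimate)
    assert "single_session_degenerate" in single.flags

    identical = far_bootstrap_ci(
        [(2, 48.0)] * 10, BootstrapConfig(n_iterations=2000, seed=1)
    )
    assert identical.upper - identical.lower == pytest.approx(0.0)


def test_bootstrap_is_deterministic_and_bracketing():
    sessions = [(i % 4, 20.0 + i) for i in range(25)]
    cfg = BootstrapConfig(n_iterations=5000, seed=9)
    a = far_bootstrap_ci(sessions, cfg)
    b = far_bootstrap_ci(sessions, cfg)
    assert (a.lower, a.upper) == (b.lower, b.upper)
    fars = [24.0 * f / h for f, h in sessions]
    assert min(fars) <= a.lower <= a.upper <= max(fars)


def test_far_ratio_symmetry_and_significance():
    sym = far_ratio_test((10, 100.0), (10, 100.0))
    assert sym.statistic == pytest.approx(0.0)
    assert sym.p_value == pytest.approx(1.0)
    zero = far_ratio_test((0, 10.0), (0, 10.0))
    assert zero.p_value == 1.0 and "zero_events" in zero.flags


def test_far_ratio_exact_matches_normal_when_counts_large():
    # With N*pi*(1-pi) >= 10 the two routes track each other closely; the
    # exact distribution's discrete steps (and its skewness at unbalanced
    # exposures) bound the achievable pointwise agreement at a couple of
    # percent for two-sided p-values.
    rng = np.random.default_rng(3)
    checked = 0
    while checked < 200:
        fa1, fa2 = int(rng.integers(0, 80)), int(rng.integers(0, 80))
        t1, t2 = float(rng.uniform(50, 500)), float(rng.uniform(50, 500))
        n = fa1 + fa2
        pi = t1 / (t1 + t2)
        if n * pi * (1 - pi) < 10:
            continue
        approx = far_ratio_test((fa1, t1), (fa2, t2))
        exact = far_ratio_test((fa1, t1), (fa2, t2), method="exact")
        assert approx.p_value == pytest.approx(exact.p_value, abs=0.025)
        checked += 1


def test_clustered_diff_identical_groups():
    group = [ClusterOutcome(f"c{i}", 2, 1) for i in range(10)]
    interval, p = clustered_diff_test(group, group)
    assert interval.estimate == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_clustered_diff_degenerate_zero_variance():
    a = singletons(5, 5, "a")
    b = singletons(5, 5, "b")
    interval, p = clustered_diff_test(a, b)
    assert p == 1.0 and "degenerate_zero_variance" in interval.flags


def test_clustered_diff_has_power():
    rng = np.random.default_rng(13)
    rejections = 0
    reps = 20
    for _ in range(reps):
        a = [
            ClusterOutcome(f"a{i}", m := int(rng.integers(1, 4)), int(rng.binomial(m, 0.95)))
            for i in range(30)
        ]
        b = [
            ClusterOutcome(f"b{i}", m := int(rng.integers(1, 4)), int(rng.binomial(m, 0.60)))
            for i in range(30)
        ]
        _, p = clustered_diff_test(a, b)
        rejections += p < 0.05
    assert rejections >= int(0.9 * reps)


def test_min_clusters_matches_brute_force_scan():
    def oracle(p, hw, icc, m):
        de = 1 + (m - 1) * icc
        k = 1
        while True:
            n_eff = k * m / de
            if wilson_halfwidth(p * n_eff, n_eff) <= hw:
                return k
            k += 1

    for p, hw, icc, m in [(0.95, 0.05, 0.0, 1.0), (0.95, 0.05, 0.2, 2.0), (0.8, 0.1, 0.4, 3.0)]:
        assert min_clusters_for_sensitivity(p, hw, icc, m) == oracle(p, hw, icc, m)


def test_min_clusters_monotone_in_icc_and_halfwidth():
    low = min_clusters_for_sensitivity(0.95, 0.05, 0.2, 2.0)
    high = min_clusters_for_sensitivity(0.95, 0.05, 0.4, 2.0)
    assert high >= low
    tight = min_clusters_for_sensitivity(0.95, 0.025, 0.2, 2.0)
    assert tight >= low


def test_far_normal_ci():
    est = far_normal_ci(357, 10296.0)
    assert est.estimate == pytest.approx(24 * 357 / 10296)
    assert est.lower < est.estimate < est.upper
    zero = far_normal_ci(0, 100.0)
    assert zero.lower == 0.0 and zero.estimate == 0.0
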