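"""Normality-gated testing framework: oracles, conventions, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctphantom.stats import (
    lilliefors_normality,
    lilliefors_statistic,
    mann_whitney_compare,
    one_way_anova,
    paired_compare,
)
from _oracles import anova_f_bruteforce, lilliefors_stat_bruteforce


def test_lilliefors_statistic_matches_bruteforce(rng):
    for _ in range(10):
        x = rng.normal(size=rng.integers(5, 60))
        assert lilliefors_statistic(x) == pytest.approx(
            lilliefors_stat_bruteforce(x), rel=1e-12
        )


def test_lilliefors_statistic_matches_statsmodels(rng):
    from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

    for _ in range(5):
        x = rng.normal(size=40)
        stat, _ = sm_lilliefors(x, dist="norm")
        assert lilliefors_statistic(x) == pytest.approx(stat, rel=1e-9)


def test_lilliefors_null_level(rng):
    """Normal samples (n=50): non-rejection in about 95% of seeded runs."""
    reject = sum(
        lilliefors_normality(rng.normal(size=50)) < 0.05 for _ in range(100)
    )
    assert reject <= 12  # 5% expected, 3 binomial SDs of slack


def test_lilliefors_power_against_exponential(rng):
    reject = sum(
        lilliefors_normality(rng.exponential(size=50)) < 0.05 for _ in range(50)
    )
    assert reject >= 35  # strongly skewed: rejected in most runs


def test_lilliefors_edge_cases():
    assert lilliefors_normality([1.0, 1.0, 1.0, 1.0]) == 0.0
    with pytest.raises(ValueError):
        lilliefors_normality([1.0, 2.0, 3.0])


def test_paired_identical_groups_p_one():
    r = paired_compare([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
    assert r.p_value == 1.0 and not r.significant


def test_paired_constant_shift_routes_to_sign_test():
    r = paired_compare([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
    assert r.test_name == "sign"
    assert r.p_value == pytest.approx(2 * 0.5**3)


def test_gate_routes_normal_to_t_and_skewed_to_wilcoxon(rng):
    a = rng.normal(size=60)
    r = paired_compare(a + 0.2, a - rng.normal(0, 0.3, size=60))
    assert r.test_name in ("paired_t", "wilcoxon")
    # heavy-tailed, strongly skewed differences: gate should reject normality
    b = rng.exponential(size=60) ** 2
    r2 = paired_compare(b, np.zeros(60))
    assert r2.test_name == "wilcoxon"
    assert r2.normality_p < 0.05


def test_wilcoxon_decision_scale_invariant(rng):
    """Doubling every observation preserves ranks, the Lilliefors gate
    (scale-free statistic) and hence the decision and p-value."""
    a = rng.exponential(size=30) ** 2
    b = np.zeros(30)
    r1 = paired_compare(a, b)
    r2 = paired_compare(2 * a, 2 * b)
    assert r1.test_name == r2.test_name == "wilcoxon"
    assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)
    assert r1.significant == r2.significant


def test_anova_identical_groups():
    r = one_way_anova([[1.0, 2.0, 3.0]] * 3)
    assert r.statistic == 0.0 and r.p_value == 1.0


def test_anova_f_matches_bruteforce(rng):
    groups = [rng.normal(loc=m, size=rng.integers(5, 15)) for m in (0, 0.5, 1.0)]
    r = one_way_anova(groups)
    assert r.statistic == pytest.approx(anova_f_bruteforce(groups), rel=1e-9)
    with pytest.raises(ValueError):
        one_way_anova([[1.0, 2.0], [3.0, 4.0]])
    with pytest.raises(ValueError):
        one_way_anova([[1.0, 2.0], [3.0, 4.0], [5.0]])


def test_gated_power_matches_analytic_paired_t(rng):
    """Paired shift of 0.5 SD at n=39 over 1000 seeded trials: the gated
    procedure's rejection rate tracks the analytic paired-t power."""
    from scipy.stats import nct, t as t_dist

    n, shift, trials = 39, 0.5, 1000
    ncp = shift * np.sqrt(n)
    tcrit = t_dist.ppf(0.975, df=n - 1)
    power = 1 - nct.cdf(tcrit, n - 1, ncp) + nct.cdf(-tcrit, n - 1, ncp)
    rejections = 0
    for _ in range(trials):
        d = rng.normal(loc=shift, size=n)
        r = paired_compare(d, np.zeros(n))
        rejections += r.significant
    rate = rejections / trials
    se = np.sqrt(power * (1 - power) / trials)
    assert abs(rate - power) < 3.5 * se + 0.01


def test_mann_whitney_available():
    r = mann_whitney_compare([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
    assert r.test_name == "mann_whitney"
    assert r.significant


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.floats(-100, 100), min_size=5, max_size=30))
def test_p_values_always_valid(xs):
    a = np.asarray(xs)
    b = a[::-1].copy()
    r = paired_compare(a, b)
    assert 0.0 <= r.p_value <= 1.0
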