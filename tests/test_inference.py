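"""Test statistics, intervals, and posteriors against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, optimize, stats
from statsmodels.stats.proportion import proportion_confint

from propde import (
    agresti_coull_ci,
    beta_posterior,
    binomial_z_test,
    credible_interval,
    poisson_lrt,
    proportion_t_test,
    ratio_t_test,
    welch_two_group_test,
)


def t_tail_by_quadrature(t, df):
    """Two-sided p-value by numerical integration of the t density."""
    tail, _ = integrate.quad(lambda x: stats.t.pdf(x, df), abs(t), np.inf)
    return 2 * tail


# ------------------------------------------------------------------ z-test


def test_binomial_z_example():
    out = binomial_z_test(0.6, 100, variance="null")
    assert out.statistic == pytest.approx(2.0)
    assert out.p_value == pytest.approx(2 * stats.norm.sf(2.0))


def test_binomial_z_null_point():
    out = binomial_z_test(0.5, 12345)
    assert out.statistic == 0.0 and out.p_value == 1.0 and not out.significant


def test_binomial_z_antisymmetry():
    lo = binomial_z_test(0.4, 500)
    hi = binomial_z_test(0.6, 500)
    assert lo.statistic == pytest.approx(-hi.statistic)
    assert lo.p_value == pytest.approx(hi.p_value)


def test_binomial_z_plug_in_degenerate_rejects():
    out = binomial_z_test(1.0, 50, variance="plug_in")
    assert math.isinf(out.statistic) and out.p_value == 0.0 and out.significant


def test_binomial_z_zero_total_is_missing():
    out = binomial_z_test(float("nan"), 0)
    assert out.missing and not out.significant


def test_binomial_z_variance_modes_close_near_half():
    null = binomial_z_test(0.52, 10000, "null")
    plug = binomial_z_test(0.52, 10000, "plug_in")
    assert null.p_value == pytest.approx(plug.p_value, abs=1e-3)


# ------------------------------------------------------------- t statistics


def test_proportion_t_flat_proportions():
    p = np.array([0.5, 0.5, 0.5, 0.5])
    out = proportion_t_test(p.mean(), p.std(ddof=1), len(p))
    assert out.statistic == 0.0 and out.p_value == 1.0


def test_proportion_t_example_against_quadrature():
    p = np.array([0.6, 0.7, 0.8])
    out = proportion_t_test(p.mean(), p.std(ddof=1), 3)
    assert out.statistic == pytest.approx(math.sqrt(3) * 2, rel=1e-12)
    assert out.df == 2
    assert out.p_value == pytest.approx(t_tail_by_quadrature(out.statistic, 2), abs=1e-9)
    assert out.p_value == pytest.approx(0.0742, abs=2e-4)


def test_proportion_t_channel_swap_antisymmetry():
    a = np.array([0.6, 0.7, 0.8])
    b = 1 - a
    out_a = proportion_t_test(a.mean(), a.std(ddof=1), 3)
    out_b = proportion_t_test(b.mean(), b.std(ddof=1), 3)
    assert out_b.statistic == pytest.approx(-out_a.statistic)
    assert out_b.p_value == pytest.approx(out_a.p_value)


def test_proportion_t_degenerate_spread():
    assert proportion_t_test(0.8, 0.0, 5).p_value == 0.0
    assert proportion_t_test(0.5, 0.0, 5).p_value == 1.0
    assert proportion_t_test(0.6, 0.1, 1).missing


def test_ratio_t_example_against_quadrature():
    lr = np.array([1.0, 2.0, 0.0])
    out = ratio_t_test(lr.mean(), lr.std(ddof=1), 3)
    assert out.statistic == pytest.approx(math.sqrt(3))
    assert out.df == 2
    assert out.p_value == pytest.approx(t_tail_by_quadrature(out.statistic, 2), abs=1e-9)
    assert out.p_value == pytest.approx(0.2254, abs=2e-4)


def test_ratio_t_null_and_missing():
    assert ratio_t_test(0.0, 0.0, 4).p_value == 1.0
    assert ratio_t_test(float("nan"), float("nan"), 0).missing


# ------------------------------------------------------------------ Welch


def test_welch_identical_groups():
    out = welch_two_group_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert out.statistic == pytest.approx(0.0) and out.p_value == pytest.approx(1.0)


def test_welch_textbook_example():
    out = welch_two_group_test([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
    assert out.statistic == pytest.approx(2 * math.sqrt(3))
    assert out.df == pytest.approx(2.0)
    assert out.p_value == pytest.approx(t_tail_by_quadrature(out.statistic, out.df), abs=1e-9)


def test_welch_label_exchange_flips_sign():
    x, y = [0.6, 0.7, 0.9], [0.4, 0.5, 0.45]
    fwd = welch_two_group_test(x, y)
    rev = welch_two_group_test(y, x)
    assert rev.statistic == pytest.approx(-fwd.statistic)
    assert rev.p_value == pytest.approx(fwd.p_value)


def test_welch_missing_groups():
    assert welch_two_group_test([1.0], [1.0, 2.0, 3.0]).missing
    nan = float("nan")
    assert welch_two_group_test([1.0, nan, nan], [1.0, 2.0, 3.0]).missing


# ------------------------------------------------------------ Poisson LRT


def brute_force_lrt(x, y):
    """LRT via generic one-dimensional likelihood maximization (no closed-form
    rate estimates)."""

    def nll(lam, counts):
        return -(np.sum(counts) * math.log(lam) - len(counts) * lam)

    def maximize(counts, lo=1e-9, hi=1e3):
        if np.sum(counts) == 0:
            return 0.0  # sup of the likelihood as lam -> 0
        res = optimize.minimize_scalar(
            lambda l: nll(l, counts), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12},
        )
        return -res.fun

    both = np.concatenate([x, y])
    return 2 * (maximize(x) + maximize(y) - maximize(both))


def test_poisson_lrt_null():
    out = poisson_lrt([5, 5], [5, 5])
    assert out.statistic == 0.0 and out.p_value == 1.0 and out.df == 1.0


def test_poisson_lrt_example_against_brute_force():
    out = poisson_lrt([10, 10], [5, 5])
    assert out.statistic == pytest.approx(2 * (20 * math.log(10 / 7.5) + 10 * math.log(5 / 7.5)))
    assert out.statistic == pytest.approx(3.3980, abs=1e-4)
    assert out.statistic == pytest.approx(brute_force_lrt([10, 10], [5, 5]), abs=1e-4)


def test_poisson_lrt_zero_condition_convention():
    out = poisson_lrt([0, 0], [3, 3])
    assert math.isfinite(out.statistic) and out.statistic > 0
    assert out.statistic == pytest.approx(brute_force_lrt([0, 0], [3, 3]), abs=1e-4)


def test_poisson_lrt_all_zero_is_missing():
    assert poisson_lrt([0, 0], [0]).missing


def test_poisson_lrt_validation():
    with pytest.raises(ValueError):
        poisson_lrt([1.5], [2])
    with pytest.raises(ValueError):
        poisson_lrt([-1], [2])
    with pytest.raises(ValueError):
        poisson_lrt([], [2])


@given(
    st.lists(st.integers(0, 30), min_size=1, max_size=6),
    st.lists(st.integers(0, 30), min_size=1, max_size=6),
)
def test_poisson_lrt_symmetry_and_nonnegativity(x, y):
    if sum(x) + sum(y) == 0:
        assert poisson_lrt(x, y).missing
        return
    fwd = poisson_lrt(x, y)
    rev = poisson_lrt(y, x)
    assert fwd.statistic >= 0.0
    assert fwd.statistic == pytest.approx(rev.statistic, abs=1e-12)
    # lane permutation within a condition changes nothing
    assert poisson_lrt(list(reversed(x)), y).statistic == pytest.approx(
        fwd.statistic, abs=1e-12
    )


# ----------------------------------------------------------------- intervals


def test_agresti_coull_symmetric_at_half():
    ci = agresti_coull_ci(10, 20, 0.95)
    assert ci.lower + ci.upper == pytest.approx(1.0)


def test_agresti_coull_zero_successes_clipped():
    ci = agresti_coull_ci(0, 20, 0.95)
    assert ci.lower == 0.0
    assert ci.upper == pytest.approx(0.1898, abs=2e-4)


def test_agresti_coull_matches_statsmodels():
    for y, m in [(0, 20), (3, 10), (50, 100), (99, 100)]:
        ci = agresti_coull_ci(y, m, 0.95)
        lo, hi = proportion_confint(y, m, alpha=0.05, method="agresti_coull")
        assert ci.lower == pytest.approx(max(0.0, lo), abs=1e-10)
        assert ci.upper == pytest.approx(min(1.0, hi), abs=1e-10)


def test_agresti_coull_degenerates_to_point_at_tiny_level():
    ci = agresti_coull_ci(7, 20, 1e-12)
    assert ci.lower == pytest.approx(0.35, abs=1e-6)
    assert ci.upper == pytest.approx(0.35, abs=1e-6)


def test_agresti_coull_coverage_by_exact_enumeration():
    """Exact coverage over all M + 1 outcomes stays near the nominal level."""
    M, level = 20, 0.95
    intervals = [agresti_coull_ci(y, M, level) for y in range(M + 1)]
    for p in (0.1, 0.3, 0.5, 0.7, 0.9):
        pmf = stats.binom.pmf(np.arange(M + 1), M, p)
        coverage = sum(
            w for w, ci in zip(pmf, intervals) if ci.lower <= p <= ci.upper
        )
        assert 0.92 <= coverage <= 1.0


def test_agresti_coull_validation():
    with pytest.raises(ValueError):
        agresti_coull_ci(-1, 20)
    with pytest.raises(ValueError):
        agresti_coull_ci(21, 20)
    with pytest.raises(ValueError):
        agresti_coull_ci(5, 20, level=1.0)


# ----------------------------------------------------------------- Bayesian


def test_beta_posterior_conjugacy():
    post = beta_posterior(3, 10, 1, 1)
    assert (post.a_post, post.b_post) == (4, 8)
    assert post.mean == pytest.approx(1 / 3)


def test_beta_posterior_validation():
    with pytest.raises(ValueError):
        beta_posterior(3, 10, a_prior=0)
    with pytest.raises(ValueError):
        beta_posterior(11, 10)


def test_credible_interval_against_density_integration():
    post = beta_posterior(3, 10, 1, 1)
    ci = credible_interval(post, 0.95)

    def cdf_by_quadrature(q):
        val, _ = integrate.quad(lambda x: stats.beta.pdf(x, 4, 8), 0, q)
        return val

    lo = optimize.brentq(lambda q: cdf_by_quadrature(q) - 0.025, 1e-9, 1 - 1e-9)
    hi = optimize.brentq(lambda q: cdf_by_quadrature(q) - 0.975, 1e-9, 1 - 1e-9)
    assert ci.lower == pytest.approx(lo, abs=1e-8)
    assert ci.upper == pytest.approx(hi, abs=1e-8)
    assert (ci.lower, ci.upper) == (pytest.approx(0.1093, abs=2e-4),
                                    pytest.approx(0.6097, abs=2e-4))


def test_flat_prior_credible_interval_approaches_agresti_coull():
    M = 10_000
    cred = credible_interval(beta_posterior(M // 2, M), 0.95)
    freq = agresti_coull_ci(M // 2, M, 0.95)
    assert cred.lower == pytest.approx(freq.lower, abs=0.01)
    assert cred.upper == pytest.approx(freq.upper, abs=0.01)


@given(st.integers(0, 50), st.integers(1, 50))
def test_outcome_invariants_binomial_z(y, extra):
    """p-values live in [0, 1]; missing outcomes are never significant."""
    M = y + extra
    out = binomial_z_test(y / M, M)
    assert not out.missing and 0.0 <= out.p_value <= 1.0
    again = out.at_level(0.5)
    assert again.significant == (out.p_value < 0.5)
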