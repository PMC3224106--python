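"""Hypothesis tests and interval estimates for paired expression summaries.

The null of no differential expression is p = 0.5 on the proportion scale and
r = 0 on the log2-ratio scale.  All p-values are two-sided; a test is
significant at level alpha when p_value < alpha, equivalently when the
absolute statistic exceeds the matching normal/t/chi-square quantile.

Degenerate zero-variance cases resolve deterministically: a statistic centred
exactly on its null with zero spread gives p = 1, any other zero-spread case
gives an infinite statistic and p = 0.  Statistics that cannot be formed at
all (too few usable pairs, zero total signal) come back as *missing* outcomes
and are never significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import special, stats


@dataclass(frozen=True)
class TestOutcome:
    """Result of a single-gene hypothesis test."""

    statistic: float
    df: float | None
    p_value: float
    method: str
    missing: bool = False
    significant: bool = False

    def at_level(self, alpha: float) -> "TestOutcome":
        """Re-evaluate significance at a different working level."""
        sig = (not self.missing) and self.p_value < alpha
        return replace(self, significant=sig)


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float
    level: float

    def __post_init__(self):
        if not self.lower <= self.upper:
            raise ValueError("lower endpoint exceeds upper endpoint")


@dataclass(frozen=True)
class BetaPosterior:
    """Conjugate beta posterior for a binomial proportion."""

    a_prior: float
    b_prior: float
    a_post: float
    b_post: float

    @property
    def mean(self) -> float:
        return self.a_post / (self.a_post + self.b_post)

    def distribution(self):
        return stats.beta(self.a_post, self.b_post)


def _missing(method: str) -> TestOutcome:
    return TestOutcome(math.nan, None, math.nan, method, missing=True, significant=False)


def _finish(statistic, df, p_value, method, alpha) -> TestOutcome:
    return TestOutcome(
        float(statistic),
        df,
        float(p_value),
        method,
        missing=False,
        significant=bool(p_value < alpha),
    )


def binomial_z_test(
    p_hat: float,
    M_total: float,
    variance: str = "null",
    alpha: float = 0.05,
) -> TestOutcome:
    """z-test of the pooled proportion against 0.5.

    Derived from the binomial hybridization model: with total signal M the
    pooled test-channel signal is Binomial(M, p) and
    ``z = (p_hat - 0.5) / sqrt(v / M)``.  ``variance="null"`` uses the
    null-hypothesis variance v = 0.25; ``variance="plug_in"`` uses
    v = p_hat(1 - p_hat).  The plug-in mode with p_hat at 0 or 1 has zero
    estimated variance and rejects outright.

    The test is exact in spirit only under the binomial model; applied to
    continuous intensities it treats them as pseudo-counts and can be wildly
    anti-conservative (its M is huge while the real replicate-to-replicate
    variance is not binomial).
    """
    method = f"zprop[{variance}]"
    if variance not in ("null", "plug_in"):
        raise ValueError(f"unknown variance mode: {variance!r}")
    if not math.isfinite(M_total) or M_total <= 0 or math.isnan(p_hat):
        return _missing(method)
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError("p_hat must lie in [0, 1]")
    v = 0.25 if variance == "null" else p_hat * (1.0 - p_hat)
    if v == 0.0:
        # plug-in variance at p_hat in {0, 1}: certain rejection
        stat = math.inf if p_hat > 0.5 else -math.inf
        return _finish(stat, None, 0.0, method, alpha)
    z = (p_hat - 0.5) / math.sqrt(v / M_total)
    p = 2.0 * special.ndtr(-abs(z))
    return _finish(z, None, p, method, alpha)


def _one_sample_t(center, null, s, n_used, method, alpha) -> TestOutcome:
    if n_used < 2 or math.isnan(center) or math.isnan(s):
        return _missing(method)
    df = n_used - 1
    if s == 0.0:
        if center == null:
            return _finish(0.0, df, 1.0, method, alpha)
        stat = math.inf if center > null else -math.inf
        return _finish(stat, df, 0.0, method, alpha)
    t = (center - null) / (s / math.sqrt(n_used))
    p = 2.0 * special.stdtr(df, -abs(t))
    return _finish(t, df, p, method, alpha)


def proportion_t_test(
    p_bar: float, s: float, n_used: int, alpha: float = 0.05
) -> TestOutcome:
    """One-sample t-test of the mean per-pair proportion against 0.5.

    ``t = (p_bar - 0.5) / (s / sqrt(n_used))`` with n_used - 1 degrees of
    freedom, where ``s`` is the sample standard deviation of the per-pair
    proportions.  This is the recommended robust statistic: it makes no
    distributional assumption beyond the CLT on the bounded per-pair
    proportions.
    """
    return _one_sample_t(p_bar, 0.5, s, n_used, "tprop", alpha)


def ratio_t_test(r_hat: float, s: float, n_used: int, alpha: float = 0.05) -> TestOutcome:
    """One-sample t-test of the mean per-pair log2-ratio against 0."""
    return _one_sample_t(r_hat, 0.0, s, n_used, "ratio", alpha)


def welch_two_group_test(x_trt, x_cont, alpha: float = 0.05) -> TestOutcome:
    """Welch unequal-variance t-test between two groups of per-array values.

    Used for control-vs-treatment designs where each array contributes one
    gene-level statistic (a per-pair proportion or log-ratio) and the groups
    are compared directly.  NaN entries (arrays where the statistic was
    undefined) are dropped; fewer than two usable values in either group
    gives a missing outcome.
    """
    method = "welch"
    x = np.asarray(x_trt, dtype=float)
    y = np.asarray(x_cont, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        return _missing(method)
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        df = float(x.size + y.size - 2)
        if x.mean() == y.mean():
            return _finish(0.0, df, 1.0, method, alpha)
        stat = math.inf if x.mean() > y.mean() else -math.inf
        return _finish(stat, df, 0.0, method, alpha)
    res = stats.ttest_ind(x, y, equal_var=False)
    return _finish(res.statistic, float(res.df), res.pvalue, method, alpha)


def poisson_lrt(x, y, alpha: float = 0.05) -> TestOutcome:
    """Likelihood-ratio test of equal Poisson rates between two conditions.

    Counts ``x`` (condition 1, one value per lane) and ``y`` (condition 2)
    are modelled as Poisson with rates lambda_1 and lambda_2 under equal
    exposure per lane; the LRT compares H0: lambda_1 = lambda_2 against the
    free alternative and is referred to chi-square with 1 df:

        LRT = 2 * [ sum(x) log(l1/l0) + sum(y) log(l2/l0) ]

    with l1, l2 the condition means, l0 the pooled mean, and the convention
    0 * log(0/.) = 0.  All-zero input in both conditions gives a missing
    outcome (the pooled rate is zero and the hypotheses are vacuous).
    """
    method = "poisson-lrt"
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    for arr in (x, y):
        if arr.size < 1:
            raise ValueError("need at least one lane per condition")
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise ValueError("counts must be finite and non-negative")
        if not np.equal(np.mod(arr, 1), 0).all():
            raise ValueError("counts must be integers")
    l1, l2 = x.mean(), y.mean()
    l0 = (x.sum() + y.sum()) / (x.size + y.size)
    if l0 == 0.0:
        return _missing(method)
    term1 = x.sum() * math.log(l1 / l0) if x.sum() > 0 else 0.0
    term2 = y.sum() * math.log(l2 / l0) if y.sum() > 0 else 0.0
    lrt = max(2.0 * (term1 + term2), 0.0)
    p = special.chdtrc(1, lrt)
    return _finish(lrt, 1.0, p, method, alpha)


def agresti_coull_ci(y: float, M: float, level: float = 0.95) -> ConfidenceInterval:
    """Agresti-Coull confidence interval for a binomial proportion.

    The sample is augmented by z^2 pseudo-trials (z the standard-normal
    quantile at (1 + level)/2): with n~ = M + z^2 and
    p~ = (y + z^2/2) / n~ the interval is p~ +/- z*sqrt(p~(1-p~)/n~),
    clipped to [0, 1].  This is the general-level augmentation form, not the
    "+2/+4" shortcut.
    """
    if M < 1:
        raise ValueError("M must be at least 1")
    if not 0 <= y <= M:
        raise ValueError("y must lie in [0, M]")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    z = stats.norm.ppf((1.0 + level) / 2.0)
    n_tilde = M + z * z
    p_tilde = (y + z * z / 2.0) / n_tilde
    half = z * math.sqrt(p_tilde * (1.0 - p_tilde) / n_tilde)
    return ConfidenceInterval(
        lower=max(0.0, p_tilde - half), upper=min(1.0, p_tilde + half), level=level
    )


def beta_posterior(
    y: float, M: float, a_prior: float = 1.0, b_prior: float = 1.0
) -> BetaPosterior:
    """Conjugate update: Beta(a, b) prior, y successes in M trials ->
    Beta(y + a, M - y + b) posterior."""
    if a_prior <= 0 or b_prior <= 0:
        raise ValueError("prior shapes must be positive")
    if not 0 <= y <= M:
        raise ValueError("y must lie in [0, M]")
    return BetaPosterior(a_prior, b_prior, y + a_prior, M - y + b_prior)


def credible_interval(post: BetaPosterior, level: float = 0.95) -> ConfidenceInterval:
    """Equal-tailed credible interval from the beta posterior quantiles."""
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    tail = (1.0 - level) / 2.0
    lo, hi = stats.beta.ppf([tail, 1.0 - tail], post.a_post, post.b_post)
    return ConfidenceInterval(lower=float(lo), upper=float(hi), level=level)
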