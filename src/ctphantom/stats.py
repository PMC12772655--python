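"""Normality-gated two-group comparisons and one-way ANOVA at the 5% level.

Two paired groups are compared with a two-tailed paired t-test when the
paired differences pass a Lilliefors normality check (p >= alpha), and with
the two-sided Wilcoxon signed-rank test otherwise.  The Lilliefors p-value
comes from a seeded Monte-Carlo null distribution (the statistic is
location-scale free, so one table per sample size is exact for any normal
null); the null tables are cached per sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "lilliefors_normality",
    "lilliefors_statistic",
    "paired_compare",
    "one_way_anova",
    "mann_whitney_compare",
]

ALPHA = 0.05

_MC_RESAMPLES = 10_000
_MC_SEED = 0x11117F02
_null_cache: dict[tuple[int, int], np.ndarray] = {}


@dataclass(frozen=True)
class TestResult:
    comparison: str
    test_name: str  # paired_t | wilcoxon | anova | sign | mann_whitney
    statistic: float
    p_value: float
    normality_p: float | None = None
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def lilliefors_statistic(values) -> float:
    """Kolmogorov-Smirnov sup-distance between the empirical CDF and a
    normal CDF with mean and SD estimated from the sample."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    sd = x.std(ddof=1)
    if sd == 0:
        return 1.0
    cdf = sps.norm.cdf(x, loc=x.mean(), scale=sd)
    upper = np.arange(1, n + 1) / n - cdf
    lower = cdf - np.arange(0, n) / n
    return float(max(upper.max(), lower.max()))


def _null_table(n: int, resamples: int = _MC_RESAMPLES) -> np.ndarray:
    key = (n, resamples)
    if key not in _null_cache:
        rng = np.random.default_rng(np.random.SeedSequence([_MC_SEED, n, resamples]))
        sims = rng.standard_normal((resamples, n))
        sims.sort(axis=1)
        mean = sims.mean(axis=1, keepdims=True)
        sd = sims.std(axis=1, ddof=1, keepdims=True)
        cdf = sps.norm.cdf((sims - mean) / sd)
        grid = np.arange(1, n + 1) / n
        upper = (grid[None, :] - cdf).max(axis=1)
        lower = (cdf - (grid[None, :] - 1.0 / n)).max(axis=1)
        _null_cache[key] = np.sort(np.maximum(upper, lower))
    return _null_cache[key]


def lilliefors_normality(differences, resamples: int = _MC_RESAMPLES) -> float:
    """Monte-Carlo Lilliefors p-value (seeded, exact under the normal null
    up to resampling error; constant samples are non-normal by convention)."""
    x = np.asarray(differences, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if x.std(ddof=1) == 0:
        return 0.0
    d = lilliefors_statistic(x)
    table = _null_table(x.size, resamples)
    n_ge = table.size - np.searchsorted(table, d, side="left")
    return float((1 + n_ge) / (1 + table.size))


def paired_compare(
    group_a, group_b, comparison: str = "", alpha: float = ALPHA,
    gate_alpha: float = ALPHA,
) -> TestResult:
    """Gated paired comparison of two equal-length, pairwise-matched groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired groups must have equal length")
    diff = a - b
    if np.all(diff == 0):
        return TestResult(comparison, "paired_t", 0.0, 1.0, None, alpha)
    if diff.std(ddof=1) == 0:
        # Constant nonzero shift: t is undefined; exact sign test.
        p = min(1.0, 2.0 * 0.5 ** diff.size)
        return TestResult(comparison, "sign", float(np.sign(diff[0]) * diff.size),
                          p, None, alpha)
    gate_p = lilliefors_normality(diff)
    if gate_p >= gate_alpha:
        t, p = sps.ttest_rel(a, b)
        return TestResult(comparison, "paired_t", float(t), float(p), gate_p, alpha)
    nz = diff[diff != 0]  # zero differences dropped (standard convention)
    mode = "exact" if nz.size <= 25 else "approx"
    w, p = sps.wilcoxon(nz, zero_method="wilcox", correction=mode == "approx",
                        mode=mode)
    return TestResult(comparison, "wilcoxon", float(w), float(p), gate_p, alpha)


def mann_whitney_compare(
    group_a, group_b, comparison: str = "", alpha: float = ALPHA
) -> TestResult:
    """Unpaired two-sided Mann-Whitney U (available behind this explicit
    entry point; the paired pipeline uses the signed-rank test)."""
    u, p = sps.mannwhitneyu(group_a, group_b, alternative="two-sided")
    return TestResult(comparison, "mann_whitney", float(u), float(p), None, alpha)


def one_way_anova(groups, comparison: str = "", alpha: float = ALPHA) -> TestResult:
    """One-way ANOVA across >= 3 groups (cross-dose HU comparisons)."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 3:
        raise ValueError("need at least three groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("every group needs at least two observations")
    grand = np.concatenate(gs)
    between = sum(g.size * (g.mean() - grand.mean()) ** 2 for g in gs)
    if between <= 1e-12 * max(grand.var(), 1e-300):
        return TestResult(comparison, "anova", 0.0, 1.0, None, alpha)
    f, p = sps.f_oneway(*gs)
    return TestResult(comparison, "anova", float(f), float(p), None, alpha)
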