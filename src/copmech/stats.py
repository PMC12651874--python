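"""Effect sizes and classical group-comparison tests.

Cohen's d uses the pooled-SD form with the first-sample-minus-second
convention (so "healthy vs patient" is negative for features elevated in
patients) and the extended magnitude ladder: negligible < 0.2, small
< 0.5, medium < 0.8, large < 1.2, very large < 2.0, huge otherwise.
Welch's unequal-variance t-test, one-way ANOVA and the tie-corrected
Kruskal-Wallis test wrap scipy with degenerate-input conventions made
explicit (identical data -> statistic 0, p = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "EffectSize", "TestResult",
    "cohens_d", "welch_t_test", "one_way_anova", "kruskal_wallis",
]

MAGNITUDE_LADDER = (
    (0.2, "negligible"),
    (0.5, "small"),
    (0.8, "medium"),
    (1.2, "large"),
    (2.0, "very large"),
)


@dataclass(frozen=True)
class EffectSize:
    d: float
    n1: int
    n2: int
    pooled_sd: float
    magnitude: str


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float


def magnitude_label(d: float) -> str:
    for cut, label in MAGNITUDE_LADDER:
        if abs(d) < cut:
            return label
    return "huge"


def cohens_d(sample1, sample2) -> EffectSize:
    """Pooled-SD standardized mean difference, sample1 minus sample2."""
    a = np.asarray(sample1, float)
    b = np.asarray(sample2, float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least two observations")
    s2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if s2 == 0.0:
        if a.mean() == b.mean():
            return EffectSize(d=0.0, n1=n1, n2=n2, pooled_sd=0.0,
                              magnitude="negligible")
        raise ValueError("zero pooled SD with unequal means: d undefined")
    d = float((a.mean() - b.mean()) / np.sqrt(s2))
    return EffectSize(d=d, n1=n1, n2=n2, pooled_sd=float(np.sqrt(s2)),
                      magnitude=magnitude_label(d))


def welch_t_test(sample1, sample2) -> TestResult:
    """Welch's unequal-variance two-sample t-test, two-sided."""
    a = np.asarray(sample1, float)
    b = np.asarray(sample2, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two observations")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return TestResult("welch_t", 0.0, float(len(a) + len(b) - 2), 1.0)
        return TestResult("welch_t", float("inf"), float(len(a) + len(b) - 2), 0.0)
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult("welch_t", float(res.statistic), float(res.df),
                      float(res.pvalue))


def one_way_anova(*groups) -> TestResult:
    """One-way fixed-effects ANOVA F-test across >= 2 groups."""
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and \
            not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    gs = [np.asarray(g, float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in gs):
        raise ValueError("each group needs at least two observations")
    means = [g.mean() for g in gs]
    within = sum(float(np.sum((g - g.mean()) ** 2)) for g in gs)
    if within == 0.0:
        if len(set(means)) == 1:
            df = (float(len(gs) - 1), float(sum(map(len, gs)) - len(gs)))
            return TestResult("anova_f", 0.0, df, 1.0)
        df = (float(len(gs) - 1), float(sum(map(len, gs)) - len(gs)))
        return TestResult("anova_f", float("inf"), df, 0.0)
    res = sps.f_oneway(*gs)
    n = sum(map(len, gs))
    return TestResult("anova_f", float(res.statistic),
                      (float(len(gs) - 1), float(n - len(gs))),
                      float(res.pvalue))


def kruskal_wallis(*groups) -> TestResult:
    """Tie-corrected Kruskal-Wallis H-test, chi-square approximation."""
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and \
            not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    gs = [np.asarray(g, float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        return TestResult("kruskal_h", 0.0, float(len(gs) - 1), 1.0)
    res = sps.kruskal(*gs)
    return TestResult("kruskal_h", float(res.statistic), float(len(gs) - 1),
                      float(res.pvalue))
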