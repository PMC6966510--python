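"""Phenotype metrics and the group-comparison statistical scheme.

Wound-healing metrics: relative wound density (RWD, %) — cell density
inside the wound relative to the density outside, baseline-subtracted —
and confluence (%).

Statistics follow the scheme used for receptor-dynamics phenotyping:
a two-sided F-test on variances selects a pooled Student t-test (equal
variances) or Welch t-test (unequal); more than two groups go to one-way
ANOVA.  Significance stars: * p < 0.05, ** p < 0.01, *** p < 0.001.
Pearson correlation and the exact upper-tail hypergeometric overlap
probability are provided for phenotype-vs-dynamics and gene-set overlap
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .membrane_sim import MaskSeries

__all__ = [
    "RWDSeries",
    "GroupComparison",
    "relative_wound_density",
    "confluence",
    "compare_groups",
    "stars_for_p",
    "type1_error_rate",
    "pearson_r",
    "hypergeometric_overlap",
]


@dataclass
class RWDSeries:
    times_h: np.ndarray
    rwd: np.ndarray  # percent; NaN where undefined


@dataclass
class GroupComparison:
    labels: tuple[str, ...]
    test: str  # 'pooled-t' | 'welch-t' | 'anova'
    statistic: float
    df: float | tuple[float, float]
    p: float  # two-tailed
    stars: str
    f_test_p: float | None  # variance-equality F-test p (two-group case)


def stars_for_p(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, else ''."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def relative_wound_density(masks: MaskSeries,
                           wound_region: np.ndarray | None = None) -> RWDSeries:
    """Relative wound density over time.

    RWD(t) = 100 * (w(t) - w(0)) / (c(t) - w(0)), where w is the
    occupied-area fraction inside the wound region (fixed from t = 0)
    and c the occupied fraction outside.  Values are clipped below at 0;
    time points with c(t) = w(0) are reported as NaN.
    """
    wound = masks.wound_region if wound_region is None else np.asarray(wound_region, bool)
    outside = ~wound
    if not wound.any() or not outside.any():
        raise ValueError("wound region must be a proper subset of the image")
    w = masks.masks[:, wound].mean(axis=1)
    c = masks.masks[:, outside].mean(axis=1)
    denom = c - w[0]
    rwd = np.where(denom != 0, 100.0 * (w - w[0]) / np.where(denom == 0, 1, denom),
                   np.nan)
    rwd = np.where(np.isnan(rwd), np.nan, np.clip(rwd, 0.0, None))
    return RWDSeries(times_h=masks.times_h.copy(), rwd=rwd)


def confluence(masks: MaskSeries) -> np.ndarray:
    """Percent of the field covered by cells at each time point."""
    return 100.0 * masks.masks.mean(axis=(1, 2))


def _f_test_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F-test for equality of variances."""
    f = np.var(a, ddof=1) / np.var(b, ddof=1)
    dfa, dfb = len(a) - 1, len(b) - 1
    p = 2.0 * min(stats.f.cdf(f, dfa, dfb), stats.f.sf(f, dfa, dfb))
    return float(min(p, 1.0))


def compare_groups(samples: list[np.ndarray], labels: list[str] | None = None,
                   alpha_var: float = 0.05) -> GroupComparison:
    """Compare groups with the F-test -> t-test / ANOVA scheme.

    Two groups: a two-sided F-test on variances at ``alpha_var`` selects
    a pooled Student t-test (variances not rejected as unequal) or a
    Welch t-test; both two-tailed.  More than two groups: one-way ANOVA.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs n >= 2")
    if labels is None:
        labels = [f"group{i}" for i in range(len(samples))]

    if len(samples) == 2:
        a, b = samples
        p_f = _f_test_p(a, b)
        equal_var = p_f >= alpha_var
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        if equal_var:
            test, df = "pooled-t", float(len(a) + len(b) - 2)
        else:
            test, df = "welch-t", float(res.df)
        return GroupComparison(labels=tuple(labels), test=test,
                               statistic=float(res.statistic), df=df,
                               p=float(res.pvalue), stars=stars_for_p(res.pvalue),
                               f_test_p=p_f)
    res = stats.f_oneway(*samples)
    k, N = len(samples), sum(len(s) for s in samples)
    return GroupComparison(labels=tuple(labels), test="anova",
                           statistic=float(res.statistic),
                           df=(float(k - 1), float(N - k)),
                           p=float(res.pvalue), stars=stars_for_p(res.pvalue),
                           f_test_p=None)


def type1_error_rate(n1: int, n2: int, sd1: float = 1.0, sd2: float = 1.0,
                     n_reps: int = 10_000, alpha: float = 0.05,
                     alpha_var: float = 0.05,
                     seed: int | None = None) -> tuple[float, float]:
    """Monte-Carlo type-I error of the F-test -> t-test selection scheme.

    Simulates ``n_reps`` pairs of normal samples with equal means and the
    given SDs, applies the same decision rule as :func:`compare_groups`
    (vectorized), and returns (rejection rate at ``alpha``, fraction of
    repetitions routed to the Welch branch).
    """
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, sd1, size=(n_reps, n1))
    b = rng.normal(0.0, sd2, size=(n_reps, n2))
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    f = va / vb
    p_f = 2.0 * np.minimum(stats.f.cdf(f, n1 - 1, n2 - 1),
                           stats.f.sf(f, n1 - 1, n2 - 1))
    p_f = np.minimum(p_f, 1.0)
    p_pooled = stats.ttest_ind(a, b, axis=1, equal_var=True).pvalue
    p_welch = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    welch = p_f < alpha_var
    p = np.where(welch, p_welch, p_pooled)
    return float(np.mean(p < alpha)), float(np.mean(welch))


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def hypergeometric_overlap(k: int, n1: int, n2: int, N: int) -> float:
    """Exact upper-tail overlap probability P[X >= k].

    X is the overlap of a random ``n2``-subset with a fixed ``n1``-subset
    of an ``N``-element universe (hypergeometric).
    """
    if not (0 <= k <= min(n1, n2) <= N) or n1 > N or n2 > N:
        raise ValueError("require 0 <= k <= min(n1, n2) <= N and n1, n2 <= N")
    return float(stats.hypergeom.sf(k - 1, N, n1, n2))
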