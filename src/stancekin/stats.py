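"""Descriptive and inferential statistics for grouped angular metrics.

Group differences in excursion metrics are tested with Welch's ANOVA (robust
to unequal variances) followed by Tukey HSD or Dunnett's T3 post hocs
depending on variance homogeneity, or nonparametrically with Kruskal-Wallis
plus Dunn's pairwise z tests. Pearson correlations carry Fisher-z confidence
intervals. Intrarater reliability uses ICC(3,1) from a two-way mixed ANOVA
with SEM = SD * sqrt(1 - ICC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate, stats

from .errors import (
    DegenerateRanksError,
    DegenerateVarianceError,
    IncompleteDesignError,
    InsufficientDataError,
    InvalidProbabilityError,
)


@dataclass
class GroupedSample:
    """Values of one metric split by the categories of one biological factor."""

    factor_name: str
    groups: list[tuple[str, np.ndarray]]

    def __post_init__(self):
        labels = [g[0] for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate group labels")
        self.groups = [(lbl, np.asarray(v, dtype=float)) for lbl, v in self.groups]
        if any(len(v) == 0 for _, v in self.groups):
            raise ValueError("empty group")

    @property
    def k(self) -> int:
        return len(self.groups)


@dataclass
class PairwiseComparison:
    label_a: str
    label_b: str
    statistic: float
    p_adjusted: float


@dataclass
class TestResult:
    statistic: float
    df1: float
    df2: float | None
    p_value: float
    method: str
    pairwise: list[PairwiseComparison] = field(default_factory=list)


def mean_ci(values: Sequence[float], level: float = 0.95) -> tuple[float, float, float]:
    """Mean with a two-sided Student-t confidence interval at ``level``."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("mean_ci needs n >= 2")
    if not (0.0 <= level < 1.0):
        raise InvalidProbabilityError(f"level must be in [0, 1), got {level}")
    m = float(np.mean(x))
    half = float(stats.t.ppf(0.5 + level / 2.0, x.size - 1) * np.std(x, ddof=1) / np.sqrt(x.size))
    return m, m - half, m + half


def _group_moments(sample: GroupedSample):
    ns = np.array([len(v) for _, v in sample.groups], dtype=float)
    means = np.array([np.mean(v) for _, v in sample.groups])
    varis = np.array([np.var(v, ddof=1) for _, v in sample.groups])
    return ns, means, varis


def welch_anova(sample: GroupedSample) -> TestResult:
    """Welch's heteroscedastic one-way ANOVA.

    F* = [sum w_j (m_j - m_w)^2 / (k-1)] / [1 + 2(k-2)/(k^2-1) * A], with
    weights w_j = n_j / s_j^2, A = sum (1 - w_j/W)^2/(n_j - 1), and
    Welch-Satterthwaite df2 = (k^2 - 1) / (3A).
    """
    if sample.k < 2:
        raise InsufficientDataError("need at least two groups")
    ns, means, varis = _group_moments(sample)
    if np.any(ns < 2):
        raise InsufficientDataError("each group needs n >= 2")
    if np.any(varis <= 0):
        bad = [lbl for (lbl, _), v in zip(sample.groups, varis) if v <= 0]
        raise DegenerateVarianceError(f"zero within-group variance in: {bad}")
    k = sample.k
    w = ns / varis
    W = w.sum()
    mw = float((w * means).sum() / W)
    num = float((w * (means - mw) ** 2).sum() / (k - 1))
    A = float((((1 - w / W) ** 2) / (ns - 1)).sum())
    denom = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * A
    f = num / denom
    df1 = k - 1
    df2 = (k**2 - 1) / (3.0 * A)
    p = float(stats.f.sf(f, df1, df2))
    return TestResult(statistic=f, df1=df1, df2=df2, p_value=p, method="welch_anova")


def levene_median(sample: GroupedSample) -> tuple[float, float]:
    """Brown-Forsythe variant of Levene's test (deviations from group medians)."""
    stat, p = stats.levene(*[v for _, v in sample.groups], center="median")
    return float(stat), float(p)


def _smm_sf(q: float, k_star: int, df: float) -> float:
    """Survival function of the studentized maximum modulus distribution.

    P(max_i |T_i| > q) for k_star independent standard normals studentized by
    a common chi(df)/sqrt(df) denominator, by numerical integration.
    """
    if q <= 0:
        return 1.0

    def integrand(u):
        return (2.0 * stats.norm.cdf(q * u) - 1.0) ** k_star * np.sqrt(df) * stats.chi.pdf(
            u * np.sqrt(df), df
        )

    cdf, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    return float(min(1.0, max(0.0, 1.0 - cdf)))


def posthoc_pairwise(sample: GroupedSample, variance_homogeneous: bool) -> list[PairwiseComparison]:
    """All-pairs post hoc comparisons after an omnibus ANOVA.

    With homogeneous variances: Tukey HSD on the pooled variance, p from the
    studentized range distribution. Otherwise Dunnett's T3: Welch-type t per
    pair, p from the studentized maximum modulus distribution on the pair's
    Welch-Satterthwaite df.
    """
    if sample.k < 2:
        raise InsufficientDataError("need at least two groups")
    ns, means, varis = _group_moments(sample)
    if np.any(ns < 2):
        raise InsufficientDataError("each group needs n >= 2")
    if np.any(varis <= 0):
        raise DegenerateVarianceError("zero within-group variance")
    k = sample.k
    labels = [lbl for lbl, _ in sample.groups]
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    out: list[PairwiseComparison] = []

    if variance_homogeneous:
        n_total = ns.sum()
        df_pool = n_total - k
        s2_pool = float(((ns - 1) * varis).sum() / df_pool)
        for i, j in pairs:
            se = np.sqrt(s2_pool / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(means[i] - means[j]) / se
            p = float(stats.studentized_range.sf(q, k, df_pool))
            out.append(PairwiseComparison(labels[i], labels[j], float(q), min(1.0, p)))
    else:
        k_star = len(pairs)
        for i, j in pairs:
            vi, vj = varis[i] / ns[i], varis[j] / ns[j]
            t = (means[i] - means[j]) / np.sqrt(vi + vj)
            df = (vi + vj) ** 2 / (vi**2 / (ns[i] - 1) + vj**2 / (ns[j] - 1))
            p = _smm_sf(abs(float(t)), k_star, df)
            out.append(PairwiseComparison(labels[i], labels[j], float(t), p))
    return out


def kruskal_dunn(sample: GroupedSample) -> TestResult:
    """Kruskal-Wallis omnibus (tie-corrected) with Dunn's pairwise z tests.

    Dunn z uses the rank-sum formulation with tie correction; pairwise p are
    Holm-adjusted.
    """
    if sample.k < 2:
        raise InsufficientDataError("need at least two groups")
    values = [v for _, v in sample.groups]
    all_v = np.concatenate(values)
    n = all_v.size
    if n < 3:
        raise InsufficientDataError("total n must be >= 3")
    if np.all(all_v == all_v[0]):
        raise DegenerateRanksError("all observations tied")

    h, p = stats.kruskal(*values)

    ranks = stats.rankdata(all_v)
    idx = np.cumsum([0] + [len(v) for v in values])
    mean_ranks = [ranks[idx[g] : idx[g + 1]].mean() for g in range(sample.k)]
    # tie correction term for Dunn's variance
    _, counts = np.unique(all_v, return_counts=True)
    tie_term = float((counts**3 - counts).sum()) / (12.0 * (n - 1))

    labels = [lbl for lbl, _ in sample.groups]
    ns = [len(v) for v in values]
    zs, raw_ps, pairs = [], [], []
    for i in range(sample.k):
        for j in range(i + 1, sample.k):
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / ns[i] + 1.0 / ns[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            zs.append(float(z))
            raw_ps.append(2.0 * float(stats.norm.sf(abs(z))))
            pairs.append((labels[i], labels[j]))
    adj = holm_adjust(raw_ps)
    pairwise = [
        PairwiseComparison(a, b, z, pa) for (a, b), z, pa in zip(pairs, zs, adj)
    ]
    return TestResult(
        statistic=float(h),
        df1=sample.k - 1,
        df2=None,
        p_value=float(p),
        method="kruskal_dunn",
        pairwise=pairwise,
    )


def pearson_ci(
    x: Sequence[float], y: Sequence[float], level: float = 0.95
) -> tuple[float, float, float, float]:
    """Pearson r with a Fisher-z confidence interval and a t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 4:
        raise InsufficientDataError("pearson_ci needs n >= 4")
    if np.var(x) == 0 or np.var(y) == 0:
        raise DegenerateVarianceError("zero variance input")
    r, p = stats.pearsonr(x, y)
    r = float(r)
    z = np.arctanh(min(1 - 1e-15, max(-1 + 1e-15, r)))
    zse = 1.0 / np.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    lo, hi = np.tanh(z - zcrit * zse), np.tanh(z + zcrit * zse)
    return r, float(lo), float(hi), float(p)


def icc_3_1(ratings: np.ndarray) -> tuple[float, float]:
    """ICC(3,1) and SEM from an n-targets x k-raters matrix.

    Two-way mixed, single measurement, consistency:
    ICC = (MSR - MSE) / (MSR + (k-1) MSE); SEM = SD * sqrt(1 - ICC) with SD
    the standard deviation of all ratings.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise ValueError("ratings must be 2-D (targets x raters)")
    if np.any(~np.isfinite(m)):
        raise IncompleteDesignError("missing cells in ratings matrix")
    n, k = m.shape
    if n < 2 or k < 2:
        raise InsufficientDataError("need >= 2 targets and >= 2 raters")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((m - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse)
    sd = float(np.std(m, ddof=1))
    sem = sd * np.sqrt(max(0.0, 1.0 - icc))
    return float(icc), float(sem)


def holm_adjust(pvals: Sequence[float]) -> list[float]:
    """Holm step-down family-wise adjustment, monotone and order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidProbabilityError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return []
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * p[idx])
        running_max = max(running_max, val)
        adj[idx] = running_max
    return [float(v) for v in adj]
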