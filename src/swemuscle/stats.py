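"""Reliability, group-comparison, correlation and a-priori power computations.

The statistical battery mirrors common practice for skewed stiffness data:

* Kruskal–Wallis rank-sum test (tie-corrected, chi-square approximation; an
  exhaustive-permutation exact mode is available at small n);
* pairwise asymptotic Wilcoxon rank-sum tests (normal approximation with
  tie-corrected variance, no continuity correction — matching R's asymptotic
  ``wilcox_test``), run only when the omnibus test is significant and with no
  multiplicity adjustment by default (Bonferroni/Holm opt-in);
* Spearman rank correlation with the conventional interpretation bands
  (|rho| > 0.75 good to excellent, 0.50-0.75 moderate to good, 0.25-0.50
  fair);
* ICC for the average of k=3 repetitions under the two-way model with
  absolute agreement (the estimator SPSS computes under "two-way mixed,
  absolute agreement, average measures"; a consistency variant is available),
  with the McGraw–Wong F-based 95% CI and SEM = pooled SD * sqrt(1 - ICC);
* a-priori sample sizes for a fixed-effects one-way ANOVA (noncentral-F
  search) and for the two-group Wilcoxon–Mann–Whitney test via the Pitman
  asymptotic-relative-efficiency method for normal parents (t-test power
  evaluated at the ARE-deflated effective sample size).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "ICCResult",
    "GroupTestResult",
    "PairResult",
    "CorrelationResult",
    "PowerSpec",
    "kruskal_wallis",
    "pairwise_wilcoxon",
    "group_comparison",
    "rank_sum_w",
    "spearman",
    "spearman_band",
    "icc_3_3",
    "anova_power",
    "anova_power_n",
    "wmw_power",
    "wmw_power_n",
    "PITMAN_ARE_NORMAL",
]

PITMAN_ARE_NORMAL = 3.0 / math.pi


# ---------------------------------------------------------------------------
# result containers


@dataclass
class PairResult:
    """One pairwise rank-sum comparison (first group's rank sum W)."""

    groups: tuple[str, str]
    w: float
    z: float
    p_value: float
    p_adjusted: float | None = None


@dataclass
class GroupTestResult:
    statistic: float
    p_value: float
    df: int | None = None
    pairs: list[PairResult] | None = None
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    band: str | None

    @property
    def defined(self) -> bool:
        return not math.isnan(self.rho)


@dataclass
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    sem: float
    model: str
    n: int
    k: int


@dataclass(frozen=True)
class PowerSpec:
    """A-priori power-analysis settings (Cohen's f; d = 2f for two groups)."""

    effect_f: float = 0.48
    alpha: float = 0.05
    power: float = 0.80
    k_groups: int = 3
    are_correction: float = PITMAN_ARE_NORMAL

    def __post_init__(self) -> None:
        if not self.effect_f > 0:
            raise ValueError("effect size f must be > 0")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.k_groups < 2:
            raise ValueError("need at least two groups")
        if not self.are_correction > 0:
            raise ValueError("ARE must be > 0")


# ---------------------------------------------------------------------------
# rank-based group comparisons


def _tie_sizes(pooled: np.ndarray) -> np.ndarray:
    _, counts = np.unique(pooled, return_counts=True)
    return counts


def _kw_h(ranks: np.ndarray, sizes: list[int], tie_term: float) -> float:
    """Tie-corrected Kruskal–Wallis H from pooled ranks split by group sizes."""
    n = len(ranks)
    h = 0.0
    start = 0
    for sz in sizes:
        h += ranks[start : start + sz].sum() ** 2 / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    denom = 1.0 - tie_term / (n**3 - n)
    return h / denom if denom > 0 else 0.0


def kruskal_wallis(samples, *, method: str = "asymptotic", alpha: float = 0.05) -> GroupTestResult:
    """Kruskal–Wallis rank-sum test across k groups.

    ``method="asymptotic"`` uses the chi-square approximation with k-1 df
    (tie-corrected H); ``method="exact"`` enumerates every assignment of the
    pooled values to the group sizes (feasible for total n up to ~12) and
    reports the exact permutation p of the observed H. Completely identical
    data across all groups yield H = 0, p = 1.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2 or any(len(s) < 1 for s in samples):
        raise ValueError("need >= 2 groups with >= 1 value each")
    pooled = np.concatenate(samples)
    k = len(samples)
    if np.all(pooled == pooled[0]):
        return GroupTestResult(statistic=0.0, p_value=1.0, df=k - 1, alpha=alpha)
    h, p = sps.kruskal(*samples)
    if method == "exact":
        p = _kw_exact_p(samples, float(h))
    elif method != "asymptotic":
        raise ValueError("method must be 'asymptotic' or 'exact'")
    return GroupTestResult(statistic=float(h), p_value=float(p), df=k - 1, alpha=alpha)


def _kw_exact_p(samples: list[np.ndarray], h_obs: float) -> float:
    pooled = np.concatenate(samples)
    n = len(pooled)
    if n > 12:
        raise ValueError("exact enumeration is limited to total n <= 12")
    ranks = sps.rankdata(pooled)
    counts = _tie_sizes(pooled)
    tie_term = float(np.sum(counts**3 - counts))
    sizes = [len(s) for s in samples]

    hits = 0
    total = 0

    def recurse(avail: tuple[int, ...], gi: int, acc: list[int]) -> None:
        nonlocal hits, total
        if gi == len(sizes) - 1:
            perm = acc + list(avail)
            h = _kw_h(ranks[perm], sizes, tie_term)
            total += 1
            if h >= h_obs - 1e-9:
                hits += 1
            return
        for combo in combinations(avail, sizes[gi]):
            rest = tuple(i for i in avail if i not in combo)
            recurse(rest, gi + 1, acc + list(combo))

    recurse(tuple(range(n)), 0, [])
    return hits / total


def rank_sum_w(x, y) -> tuple[float, float, float]:
    """Rank sum W of the first sample, its z under H0 (tie-corrected variance,
    no continuity correction), and the two-sided asymptotic p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n1].sum())
    mean = n1 * (n + 1) / 2.0
    counts = _tie_sizes(pooled)
    tie = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:
        return w, 0.0, 1.0
    z = (w - mean) / math.sqrt(var)
    return w, z, 2.0 * sps.norm.sf(abs(z))


def pairwise_wilcoxon(
    samples,
    labels=None,
    *,
    method: str = "asymptotic",
    adjust: str | None = None,
) -> list[PairResult]:
    """All pairwise two-group rank-sum comparisons.

    No multiplicity adjustment by default; ``adjust`` accepts ``"bonferroni"``
    or ``"holm"``. ``method="exact"`` replaces the asymptotic p by the exact
    Mann–Whitney null distribution (small samples, no ties assumption relaxed
    by the permutation distribution scipy enumerates).
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if any(len(s) == 0 for s in samples):
        raise ValueError("groups must be non-empty")
    if labels is None:
        labels = [str(i + 1) for i in range(len(samples))]
    out: list[PairResult] = []
    for i, j in combinations(range(len(samples)), 2):
        w, z, p = rank_sum_w(samples[i], samples[j])
        if method == "exact":
            p = float(
                sps.mannwhitneyu(samples[i], samples[j], method="exact").pvalue
            )
        elif method != "asymptotic":
            raise ValueError("method must be 'asymptotic' or 'exact'")
        out.append(PairResult(groups=(labels[i], labels[j]), w=w, z=z, p_value=p))
    if adjust is not None:
        _adjust_pvalues(out, adjust)
    return out


def _adjust_pvalues(pairs: list[PairResult], how: str) -> None:
    m = len(pairs)
    if how == "bonferroni":
        for pr in pairs:
            pr.p_adjusted = min(1.0, pr.p_value * m)
    elif how == "holm":
        order = np.argsort([pr.p_value for pr in pairs])
        running = 0.0
        for rank, idx in enumerate(order):
            adj = min(1.0, (m - rank) * pairs[idx].p_value)
            running = max(running, adj)
            pairs[idx].p_adjusted = running
    else:
        raise ValueError("adjust must be 'bonferroni' or 'holm'")


def group_comparison(
    samples,
    labels=None,
    *,
    alpha: float = 0.05,
    adjust: str | None = None,
    force_pairwise: bool = False,
) -> GroupTestResult:
    """Omnibus Kruskal–Wallis followed, when significant (strict p < alpha),
    by pairwise asymptotic Wilcoxon rank-sum tests."""
    res = kruskal_wallis(samples, alpha=alpha)
    if res.significant or force_pairwise:
        res.pairs = pairwise_wilcoxon(samples, labels, adjust=adjust)
    return res


# ---------------------------------------------------------------------------
# correlation


def spearman_band(rho: float) -> str | None:
    """Interpretation band of |rho|: >0.75 good to excellent; [0.50, 0.75]
    moderate to good; [0.25, 0.50) fair; below 0.25 none."""
    if math.isnan(rho):
        return None
    a = abs(rho)
    if a > 0.75:
        return "good_to_excellent"
    if a >= 0.50:
        return "moderate_to_good"
    if a >= 0.25:
        return "fair"
    return "below_fair"


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties and asymptotic p.

    Incomplete pairs are dropped; fewer than 3 complete pairs is an error;
    zero variance in either variable yields an undefined (NaN) coefficient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(rho=math.nan, p_value=math.nan, n=n, band=None)
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p_value=float(p), n=n, band=spearman_band(float(rho)))


# ---------------------------------------------------------------------------
# reliability


def icc_3_3(data, *, variant: str = "absolute_agreement", alpha: float = 0.05) -> ICCResult:
    """Average-measures ICC of an n-subjects x k-repetitions table.

    ``variant="absolute_agreement"`` computes the two-way absolute-agreement
    average-measures estimator, ``(MSR - MSE) / (MSR + (MSC - MSE)/n)`` —
    what SPSS reports under "two-way mixed, absolute agreement, average
    measures" for k repetitions — with the McGraw–Wong F-based CI.
    ``variant="consistency"`` gives ``(MSR - MSE)/MSR`` instead. Rows with
    missing values are deleted listwise. SEM = pooled SD * sqrt(1 - ICC),
    where the pooled SD is the square root of the mean within-repetition
    between-subject variance.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be n subjects x k repetitions")
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 2:
        raise ValueError("need at least 2 complete subjects")
    if n < 5:
        logger.warning("ICC on n=%d subjects; interpret with caution", n)
    if k != 3:
        logger.info("ICC computed for k=%d repetitions (design uses k=3)", k)

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = max(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    if variant == "consistency":
        if msr <= 0:
            icc = math.nan
            ci = (math.nan, math.nan)
        else:
            icc = (msr - mse) / msr
            if mse == 0:
                ci = (icc, icc)
            else:
                f_obs = msr / mse
                df2 = (n - 1) * (k - 1)
                fl = f_obs / sps.f.ppf(1 - alpha / 2, n - 1, df2)
                fu = f_obs * sps.f.ppf(1 - alpha / 2, df2, n - 1)
                ci = (1 - 1 / fl, 1 - 1 / fu)
        model = f"two-way mixed, consistency, average of k={k}"
    elif variant == "absolute_agreement":
        denom = msr + (msc - mse) / n
        icc = (msr - mse) / denom if denom > 0 else math.nan
        if mse == 0 and msc == 0:
            ci = (icc, icc)
        else:
            icc_single = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
            fj = msc / mse if mse > 0 else math.inf
            a_ = k * icc_single * fj + n * (1 + (k - 1) * icc_single) - k * icc_single
            vn = (n - 1) * (k - 1) * a_**2
            vd = (n - 1) * k**2 * icc_single**2 * fj**2 + (
                n * (1 + (k - 1) * icc_single) - k * icc_single
            ) ** 2
            v = vn / vd
            f2u = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f2l = sps.f.ppf(1 - alpha / 2, v, n - 1)
            l2 = (
                n * (msr - f2u * mse)
                / (f2u * (k * msc + (k * n - k - n) * mse) + n * msr)
            )
            u2 = (
                n * (f2l * msr - mse)
                / (k * msc + (k * n - k - n) * mse + n * f2l * msr)
            )
            ci = (
                l2 * k / (1 + l2 * (k - 1)),
                u2 * k / (1 + u2 * (k - 1)),
            )
        model = f"two-way mixed, absolute agreement, average of k={k}"
    else:
        raise ValueError("variant must be 'absolute_agreement' or 'consistency'")

    pooled_sd = math.sqrt(float(np.mean(x.var(axis=0, ddof=1))))
    sem = pooled_sd * math.sqrt(max(1 - icc, 0.0)) if not math.isnan(icc) else math.nan
    return ICCResult(icc=float(icc), ci95=(float(ci[0]), float(ci[1])), sem=sem, model=model, n=n, k=k)


# ---------------------------------------------------------------------------
# a-priori power


def anova_power(n_total: int, spec: PowerSpec) -> float:
    """Power of the fixed-effects one-way ANOVA F test at total N.

    Noncentrality lambda = f^2 * N, df1 = k - 1, df2 = N - k.
    """
    k = spec.k_groups
    df1, df2 = k - 1, n_total - k
    if df2 < 1:
        return 0.0
    crit = sps.f.ppf(1 - spec.alpha, df1, df2)
    return float(1 - sps.ncf.cdf(crit, df1, df2, spec.effect_f**2 * n_total))


def anova_power_n(spec: PowerSpec, *, n_max: int = 100000) -> int:
    """Smallest total N whose one-way ANOVA power reaches the target."""
    for n in range(spec.k_groups + 1, n_max + 1):
        if anova_power(n, spec) >= spec.power:
            return n
    raise ValueError(f"power {spec.power} unreachable below N={n_max}")


def _t_power_effective(n_eff: float, d: float, alpha: float) -> float:
    """Two-sided two-sample t-test power at (possibly fractional) total n."""
    if n_eff <= 2:
        return 0.0
    df = n_eff - 2
    ncp = d * math.sqrt(n_eff / 4.0)
    crit = sps.t.ppf(1 - alpha / 2, df)
    return float(1 - sps.nct.cdf(crit, df, ncp) + sps.nct.cdf(-crit, df, ncp))


def wmw_power(n_total: int, spec: PowerSpec) -> float:
    """Approximate Wilcoxon–Mann–Whitney power at total N (1:1 allocation)
    via the ARE method: t-test power at the effective size N * ARE."""
    d = 2.0 * spec.effect_f
    return _t_power_effective(n_total * spec.are_correction, d, spec.alpha)


def wmw_power_n(spec: PowerSpec, *, n_max: int = 100000) -> int:
    """Smallest even total N whose ARE-corrected WMW power reaches the target.

    With ``are_correction=1`` this reduces to the exact noncentral-t
    two-sample t-test sample size (even N, 1:1 allocation).
    """
    for n in range(4, n_max + 1, 2):
        if wmw_power(n, spec) >= spec.power:
            return n
    raise ValueError(f"power {spec.power} unreachable below N={n_max}")
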