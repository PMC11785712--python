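"""Nonparametric statistics used throughout the pipeline.

Implements the Mann-Kendall trend test with tie-corrected variance, the
Theil-Sen slope estimator with a rank-based confidence interval, first-order
partial correlation, the Kruskal-Wallis rank test, the Conover-Iman post-hoc
comparison, and the critical Pearson-correlation threshold for a given sample
size.  These are written out explicitly (rather than wrapping a library)
because the exact tie handling, continuity correction and confidence
construction are part of the method being exercised; library versions are
used only as cross-checks in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TrendResult",
    "mann_kendall",
    "theil_sen",
    "partial_correlation",
    "kruskal_wallis",
    "conover_iman",
    "critical_r",
    "InsufficientDataError",
    "DegenerateControlError",
]


class InsufficientDataError(ValueError):
    """Raised when a series is too short for the requested statistic."""


class DegenerateControlError(ValueError):
    """Raised when the control variable is collinear with an input."""


@dataclass(frozen=True)
class TrendResult:
    """Joint Mann-Kendall / Theil-Sen summary for one series.

    Attributes
    ----------
    S : int
        Mann-Kendall score, the number of concordant minus discordant pairs.
    var_s : float
        Variance of ``S`` under the null, with tie-group correction.
    z : float
        Standard normal deviate (continuity-corrected).
    p_two_sided : float
        Two-sided p-value from the normal approximation.
    sen_slope, sen_intercept : float
        Theil-Sen slope (units per time step) and median intercept.
    slope_ci : tuple of float
        Rank-based confidence interval for the slope.
    ci_level : float
        Confidence level of ``slope_ci``.
    n : int
        Series length.
    """

    S: int
    var_s: float
    z: float
    p_two_sided: float
    sen_slope: float
    sen_intercept: float
    slope_ci: tuple[float, float]
    ci_level: float = 0.95
    n: int = 0


def _as_1d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(a)):
        raise ValueError("series contains non-finite values")
    return a


def mann_kendall(series, times=None, ci_level: float = 0.95) -> TrendResult:
    """Mann-Kendall trend test with tie correction plus Theil-Sen slope.

    ``S = sum_{i<j} sign(x_j - x_i)``; the variance subtracts the usual
    tie-group term ``t(t-1)(2t+5)`` for each group of ``t`` equal values.
    The z statistic applies the +/-1 continuity correction and the p-value
    uses the two-sided normal approximation, appropriate for series of a
    couple of dozen points.
    """
    x = _as_1d(series)
    n = x.size
    if n < 4:
        raise InsufficientDataError(f"need n >= 4, got n={n}")
    if times is None:
        t = np.arange(n, dtype=float)
    else:
        t = _as_1d(times)
        if t.size != n:
            raise ValueError("times and series lengths differ")

    diff = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diff, k=1).sum())

    _, counts = np.unique(x, return_counts=True)
    tie_term = float(np.sum(counts * (counts - 1) * (2 * counts + 5)))
    var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0

    if var_s > 0:
        if s > 0:
            z = (s - 1) / np.sqrt(var_s)
        elif s < 0:
            z = (s + 1) / np.sqrt(var_s)
        else:
            z = 0.0
    else:
        z = 0.0
    p = 2.0 * sps.norm.sf(abs(z))

    slope, intercept, ci = theil_sen(x, t, ci_level=ci_level, var_s=var_s)
    return TrendResult(
        S=s,
        var_s=var_s,
        z=float(z),
        p_two_sided=float(min(p, 1.0)),
        sen_slope=slope,
        sen_intercept=intercept,
        slope_ci=ci,
        ci_level=ci_level,
        n=n,
    )


def theil_sen(
    series,
    times=None,
    ci_level: float = 0.95,
    var_s: float | None = None,
) -> tuple[float, float, tuple[float, float]]:
    """Theil-Sen estimator: median of all pairwise slopes.

    Pairs with duplicated time values are excluded.  The confidence interval
    is Sen's rank-based construction on the ordered pairwise slopes, with the
    rank offset ``C = z * sqrt(var(S))``.

    Returns ``(slope, intercept, (ci_lo, ci_hi))`` where the intercept is
    ``median(x - slope * t)``.
    """
    x = _as_1d(series)
    n = x.size
    if times is None:
        t = np.arange(n, dtype=float)
    else:
        t = _as_1d(times)
    if n < 2:
        raise InsufficientDataError("need at least two points")

    ii, jj = np.triu_indices(n, k=1)
    dt = t[jj] - t[ii]
    keep = dt != 0
    if not keep.any():
        raise InsufficientDataError("all time values identical")
    slopes = np.sort((x[jj] - x[ii])[keep] / dt[keep])
    slope = float(np.median(slopes))
    intercept = float(np.median(x - slope * t))

    if var_s is None:
        _, counts = np.unique(x, return_counts=True)
        tie_term = float(np.sum(counts * (counts - 1) * (2 * counts + 5)))
        var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    n_slopes = slopes.size
    c = sps.norm.ppf(0.5 + ci_level / 2.0) * np.sqrt(max(var_s, 0.0))
    m1 = int(np.floor((n_slopes - c) / 2.0))
    m2 = int(np.ceil((n_slopes + c) / 2.0))
    lo = float(slopes[max(m1, 0)])
    hi = float(slopes[min(m2, n_slopes - 1)])
    return slope, intercept, (min(lo, slope), max(hi, slope))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return np.nan
    return float(a @ b / denom)


def partial_correlation(x, y, control) -> tuple[float, float]:
    """First-order partial correlation of x and y controlling for one variable.

    Uses ``r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))`` and a
    t-test with ``n - 3`` degrees of freedom.  Controlling for the observation
    year in this way removes shared linear trends before association is judged.
    """
    xa, ya, za = _as_1d(x), _as_1d(y), _as_1d(control)
    n = xa.size
    if not (ya.size == n == za.size):
        raise ValueError("x, y and control must have equal length")
    if n < 4:
        raise InsufficientDataError(f"need n >= 4, got n={n}")

    r_xy = _pearson(xa, ya)
    r_xz = _pearson(xa, za)
    r_yz = _pearson(ya, za)
    if not np.isfinite(r_xz) or not np.isfinite(r_yz) or min(1 - r_xz**2, 1 - r_yz**2) <= 1e-12:
        raise DegenerateControlError("x or y is collinear with the control variable")
    r = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if abs(r) >= 1.0:
        return r, 0.0
    tstat = r * np.sqrt(df / (1 - r**2))
    p = 2.0 * sps.t.sf(abs(tstat), df)
    return r, float(p)


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H with mid-rank tie correction.

    ``H = 12/(N(N+1)) * sum R_g^2/n_g - 3(N+1)`` divided by
    ``1 - sum(t^3 - t)/(N^3 - N)`` over tie groups; p from chi-square with
    ``k - 1`` degrees of freedom.
    """
    arrs = [_as_1d(g) for g in groups]
    k = len(arrs)
    if k < 2 or any(a.size == 0 for a in arrs):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate(arrs)
    n_total = pooled.size
    if n_total < 3:
        raise InsufficientDataError("need total n >= 3")
    ranks = _midranks(pooled)
    h = 0.0
    start = 0
    for a in arrs:
        r_sum = ranks[start : start + a.size].sum()
        h += r_sum**2 / a.size
        start += a.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n_total**3 - n_total)
    if correction <= 0:  # all observations identical
        return 0.0, 1.0
    h /= correction
    p = float(sps.chi2.sf(h, k - 1))
    return float(h), p


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: int
    group_b: int
    t: float
    p_raw: float
    p_adjusted: float
    significant: bool


def conover_iman(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    adjust: str = "holm",
) -> list[PairwiseComparison]:
    """Conover-Iman pairwise rank comparisons following a Kruskal-Wallis test.

    Each pair is compared with a t statistic on mean ranks using the pooled
    rank variance ``S^2`` and the factor ``(N - 1 - H)/(N - k)``, with
    ``N - k`` degrees of freedom.  Raw and multiplicity-adjusted p-values are
    both reported; Holm is the default adjustment.
    """
    arrs = [_as_1d(g) for g in groups]
    k = len(arrs)
    h, _ = kruskal_wallis(arrs)
    pooled = np.concatenate(arrs)
    n_total = pooled.size
    ranks = _midranks(pooled)
    sizes = np.array([a.size for a in arrs])
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array(
        [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(k)]
    )
    s2 = (np.sum(ranks**2) - n_total * (n_total + 1) ** 2 / 4.0) / (n_total - 1)
    df = n_total - k
    scale = s2 * (n_total - 1 - h) / df if df > 0 else np.nan

    pairs = list(combinations(range(k), 2))
    tvals, pvals = [], []
    for i, j in pairs:
        denom = np.sqrt(scale * (1.0 / sizes[i] + 1.0 / sizes[j]))
        tval = 0.0 if denom == 0 else (mean_ranks[i] - mean_ranks[j]) / denom
        tvals.append(float(tval))
        pvals.append(float(2.0 * sps.t.sf(abs(tval), df)) if df > 0 else 1.0)
    if adjust in (None, "none"):
        adj = list(pvals)
        reject = [p < alpha for p in pvals]
    else:
        reject, adj, _, _ = multipletests(pvals, alpha=alpha, method=adjust)
        adj = list(adj)
        reject = list(reject)
    return [
        PairwiseComparison(i, j, t, p, pa, bool(r))
        for (i, j), t, p, pa, r in zip(pairs, tvals, pvals, adj, reject)
    ]


def critical_r(n: int, alpha: float = 0.05, two_sided: bool = True) -> float:
    """Smallest |Pearson r| significant at level alpha for sample size n.

    ``r* = t* / sqrt(df + t*^2)`` with ``df = n - 2``.  At n = 25 and
    alpha = 0.05 this is 0.396, the usual +/-0.40 masking threshold for a
    25-year correlation map.
    """
    if n < 3:
        raise InsufficientDataError("need n >= 3")
    df = n - 2
    q = 1 - alpha / 2 if two_sided else 1 - alpha
    t_star = sps.t.ppf(q, df)
    return float(t_star / np.sqrt(df + t_star**2))
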