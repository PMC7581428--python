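"""Shared deterministic statistical primitives.

Every downstream stage (instability, expression, rescue, pathology) funnels
its hypothesis tests through the four operations here so that conventions —
two-sided unpaired t-tests, Pearson correlation with a t-transform p-value,
Benjamini-Hochberg step-up adjustment, and one-sided (upper-tail) Fisher
exact tests — are implemented exactly once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "FisherResult",
    "two_sample_ttest",
    "pearson_correlation",
    "bh_adjust",
    "fisher_one_sided",
]


@dataclass(frozen=True)
class GroupComparison:
    """Two-group mean comparison via an unpaired two-sided t-test."""

    mean_a: float
    mean_b: float
    mean_diff: float
    ci95_low: float
    ci95_high: float
    t_stat: float
    df: float
    p_two_sided: float
    n_a: int
    n_b: int
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    """Sample Pearson correlation with a two-sided t-transform p-value."""

    r: float
    p_two_sided: float
    n: int


@dataclass(frozen=True)
class FisherResult:
    """One-sided (over-representation) Fisher exact test on a 2x2 overlap."""

    overlap_k: int
    query_size_K: int
    draw_size_n: int
    universe_N: int
    odds_ratio: float
    p_one_sided: float


def two_sample_ttest(
    values_a: Sequence[float],
    values_b: Sequence[float],
    variance_mode: Literal["pooled", "welch"] = "pooled",
) -> GroupComparison:
    """Two-sided unpaired t-test comparing the means of two groups.

    Parameters
    ----------
    values_a, values_b
        Per-unit measurements (>= 2 each).
    variance_mode
        ``"pooled"`` for the classic equal-variance Student test (default),
        ``"welch"`` for the unequal-variance Welch test.

    Returns
    -------
    GroupComparison
        Includes the mean difference (a - b), a 95% CI on it computed from
        the same degrees of freedom as the test, and the two-sided p-value.

    Notes
    -----
    If both groups have zero variance the test statistic is undefined; by
    convention the result is flagged ``degenerate`` with p = 1 when the means
    are equal and p = 0 otherwise, so genome-wide per-gene loops never abort.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("inputs must be one-dimensional")
    n_a, n_b = a.size, b.size
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 values")
    if variance_mode not in ("pooled", "welch"):
        raise ValueError(f"unknown variance_mode: {variance_mode!r}")

    mean_a = float(a.mean())
    mean_b = float(b.mean())
    diff = mean_a - mean_b
    var_a = float(a.var(ddof=1))
    var_b = float(b.var(ddof=1))

    if var_a == 0.0 and var_b == 0.0:
        if diff == 0.0:
            p, t_stat = 1.0, 0.0
        else:
            p, t_stat = 0.0, math.copysign(math.inf, diff)
        df = float(n_a + n_b - 2)
        return GroupComparison(
            mean_a, mean_b, diff, diff, diff, t_stat, df, p, n_a, n_b,
            degenerate=True,
        )

    if variance_mode == "pooled":
        df = float(n_a + n_b - 2)
        sp2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
        se = math.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    else:
        se2_a = var_a / n_a
        se2_b = var_b / n_b
        se = math.sqrt(se2_a + se2_b)
        df = (se2_a + se2_b) ** 2 / (
            se2_a**2 / (n_a - 1) + se2_b**2 / (n_b - 1)
        )

    t_stat = diff / se
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    t_crit = stats.t.ppf(0.975, df)
    return GroupComparison(
        mean_a,
        mean_b,
        diff,
        diff - t_crit * se,
        diff + t_crit * se,
        float(t_stat),
        float(df),
        float(min(p, 1.0)),
        n_a,
        n_b,
    )


def pearson_correlation(
    x: Sequence[float], y: Sequence[float]
) -> CorrelationResult:
    """Sample Pearson r with a two-sided p from the t transform (n-2 df)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be one-dimensional and equal length")
    n = xa.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if xa.var() == 0.0 or ya.var() == 0.0:
        raise ValueError("zero variance in x or y")
    res = stats.pearsonr(xa, ya)
    return CorrelationResult(float(res.statistic), float(res.pvalue), n)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Each output is clipped to ``[input, 1]`` and the procedure is idempotent
    on already-adjusted vectors.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.empty(m, dtype=float)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted


def fisher_one_sided(
    overlap_k: int, query_K: int, draw_n: int, universe_N: int
) -> FisherResult:
    """Upper-tail hypergeometric test Pr(X >= k) for overlap enrichment.

    The 2x2 table is (query vs. not-query) x (drawn vs. not-drawn) within a
    universe of ``universe_N`` items.
    """
    k, K, n, N = (int(overlap_k), int(query_K), int(draw_n), int(universe_N))
    if min(k, K, n, N) < 0:
        raise ValueError("counts must be nonnegative")
    if k > min(K, n) or K > N or n > N:
        raise ValueError(
            f"inconsistent 2x2 counts: k={k}, K={K}, n={n}, N={N}"
        )
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    # odds ratio of the realized table; inf when a zero cell makes it so
    a, b_, c = k, K - k, n - k
    d = N - K - n + k
    if b_ * c == 0:
        odds = math.inf if (a * d > 0 or b_ + c == 0) else 0.0
    else:
        odds = (a * d) / (b_ * c)
    return FisherResult(k, K, n, N, odds, min(p, 1.0))
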