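"""Statistical primitives: Fisher's exact test, Student's t, BH-FDR, Pearson's r.

All routines are implemented against their closed-form definitions so the
package's numerical behaviour does not inherit any particular third-party
convention (notably the sample cross-product odds ratio versus the
conditional-MLE odds ratio returned by some Fisher implementations).
Distribution functions (hypergeometric pmf, Student's t CDF) come from scipy.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "fisher_exact_two_sided",
    "odds_ratio",
    "t_test",
    "bh_adjust",
    "pearson_r",
]

# Relative tolerance when comparing hypergeometric probabilities to the
# observed table's probability in the two-sided tail sum.  Guards against
# floating-point noise excluding tables that are exactly as extreme.
_REL_TOL = 1.0 + 1e-7


def _validate_table(table) -> tuple[int, int, int, int]:
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"contingency table must be 2x2, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("contingency table contains non-finite entries")
    if np.any(arr < 0):
        raise ValueError("contingency table entries must be non-negative")
    if not np.all(arr == np.floor(arr)):
        raise ValueError("contingency table entries must be integers")
    a, b, c, d = (int(x) for x in arr.ravel())
    return a, b, c, d


def odds_ratio(table) -> float:
    """Sample (cross-product) odds ratio a*d / (b*c).

    When any cell is zero the Haldane–Anscombe correction adds 0.5 to every
    cell, keeping the ratio finite and non-zero.
    """
    a, b, c, d = _validate_table(table)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_exact_two_sided(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    The p-value is the sum of hypergeometric probabilities of all tables
    (with the same margins) whose probability does not exceed that of the
    observed table.  Returns ``(p_value, odds_ratio)`` with the sample
    odds ratio of :func:`odds_ratio`.
    """
    a, b, c, d = _validate_table(table)
    or_ = odds_ratio(table)

    M = a + b + c + d  # population size
    n_good = a + b     # first-row margin
    n_draw = a + c     # first-column margin
    if M == 0:
        return 1.0, or_

    lo = max(0, n_draw - (M - n_good))
    hi = min(n_good, n_draw)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, M, n_good, n_draw)
    p_obs = pmf[a - lo]
    included = pmf <= p_obs * _REL_TOL
    if included.all():
        return 1.0, or_
    p = float(pmf[included].sum())
    return min(p, 1.0), or_


def t_test(
    x: Sequence[float],
    y: Sequence[float],
    *,
    paired: bool = False,
    welch: bool = False,
) -> tuple[float, float, float]:
    """Two-tailed Student's t-test.

    Unpaired uses the pooled-variance statistic (or Welch when requested);
    paired is a one-sample test on the differences.  Degenerate inputs with
    zero variance follow the convention t = 0, p = 1 when the means are
    equal (e.g. identical paired samples), and p = 0 otherwise.

    Returns ``(t, df, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("t_test expects 1-D samples")
    if paired:
        if x.size != y.size:
            raise ValueError("paired t-test requires equal-length samples")
        if x.size < 2:
            raise ValueError("paired t-test requires at least 2 pairs")
        diff = x - y
        n = diff.size
        df = n - 1
        sd = diff.std(ddof=1)
        mean = diff.mean()
        if sd == 0.0:
            return (0.0, float(df), 1.0) if mean == 0.0 else (math.inf * np.sign(mean), float(df), 0.0)
        t = mean / (sd / math.sqrt(n))
    else:
        if x.size < 2 or y.size < 2:
            raise ValueError("unpaired t-test requires at least 2 observations per group")
        nx, ny = x.size, y.size
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        dmean = x.mean() - y.mean()
        if welch:
            se2 = vx / nx + vy / ny
            if se2 == 0.0:
                df = nx + ny - 2
                return (0.0, float(df), 1.0) if dmean == 0.0 else (math.inf * np.sign(dmean), float(df), 0.0)
            df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
            t = dmean / math.sqrt(se2)
        else:
            df = nx + ny - 2
            sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
            if sp2 == 0.0:
                return (0.0, float(df), 1.0) if dmean == 0.0 else (math.inf * np.sign(dmean), float(df), 0.0)
            t = dmean / math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order preserved.

    adj(i) = min_{j : p_(j) >= p_(i)} p_(j) * n / rank(j), capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("bh_adjust expects a non-empty 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.empty(n)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with two-tailed p via the t transform.

    p is computed from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of
    freedom; |r| = 1 maps to p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("pearson_r requires equal-length vectors")
    n = x.size
    if n < 3:
        raise ValueError("pearson_r requires at least 3 observations")
    xd = x - x.mean()
    yd = y - y.mean()
    sxx = float(xd @ xd)
    syy = float(yd @ yd)
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("pearson_r is undefined for zero-variance input")
    r = float(xd @ yd) / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return r, float(min(p, 1.0))
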