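"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity from its mathematical definition via a
route deliberately different from the package implementation (enumeration
with exact rational arithmetic, explicit loops, direct formulas).
"""

from math import comb, log2, sqrt


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive hypergeometric enumeration of the two-sided Fisher p-value."""
    M = a + b + c + d
    n_good = a + b
    n_draw = a + c
    lo = max(0, n_draw - (M - n_good))
    hi = min(n_good, n_draw)

    def pmf(k: int) -> float:
        return comb(n_good, k) * comb(M - n_good, n_draw - k) / comb(M, n_draw)

    p_obs = pmf(a)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-7))


def bh_direct(p: list[float]) -> list[float]:
    """BH step-up by the literal min-over-tail definition (O(n^2))."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    rank = {idx: r + 1 for r, idx in enumerate(order)}
    adj = []
    for i in range(n):
        # min over all j with p_j >= p_i of p_j * n / rank_j
        candidates = [p[j] * n / rank[j] for j in range(n) if p[j] >= p[i]]
        adj.append(min(1.0, min(candidates)))
    return adj


def pooled_t(x: list[float], y: list[float]) -> tuple[float, int]:
    """Pooled-variance Student's t statistic and df from the textbook formula."""
    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    df = nx + ny - 2
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
    t = (mx - my) / sqrt(sp2 * (1 / nx + 1 / ny))
    return t, df


def pearson_direct(x: list[float], y: list[float]) -> float:
    """Pearson r from the covariance formula with explicit loops."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / sqrt(sxx * syy)


def specificity_direct(x_row: list[float], lineage: int) -> float:
    """Specificity index from per-gene scalar arithmetic."""
    total = sum(x_row)
    p = [v / total for v in x_row]
    entropy = -sum(v * log2(v) for v in p if v > 0)
    if p[lineage] == 0:
        return float("inf")
    return entropy - log2(p[lineage])
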