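"""Two-sided Mann-Whitney U p-values with a cached exact null.

Small per-timepoint cells (4-10 animals per sex) make the normal
approximation crude, so the exact permutation distribution of U is used
whenever the combined sample size is at most ``EXACT_MAX_N`` and there
are no ties; otherwise the normal approximation with tie correction and
continuity correction applies.  The exact null CDF is computed once per
(n1, n2) by the standard counting recurrence

    N(u; n1, n2) = N(u - n2; n1 - 1, n2) + N(u; n1, n2 - 1)

and cached, which makes permutation studies cheap.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.stats import norm, rankdata

EXACT_MAX_N = 16  # combined-sample cutoff for the exact null


@lru_cache(maxsize=256)
def exact_u_cdf(n1: int, n2: int) -> np.ndarray:
    """P(U <= u) for u = 0..n1*n2 under the tie-free null."""
    # counts[a][b] -> array of #assignments with each U value
    prev_row: list[np.ndarray] = [np.ones(1) for _ in range(n2 + 1)]
    for a in range(1, n1 + 1):
        row: list[np.ndarray] = [np.ones(1)]
        for b in range(1, n2 + 1):
            out = np.zeros(a * b + 1)
            out[b:] += prev_row[b]  # new A-item ranked above all b B-items
            out[: a * (b - 1) + 1] += row[b - 1]
            row.append(out)
        prev_row = row
    counts = prev_row[n2]
    return np.cumsum(counts) / counts.sum()


def exact_two_sided_p(u1, n1: int, n2: int) -> np.ndarray:
    """Exact two-sided p for statistic U1 of the first sample (vectorized).

    p = min(1, 2 * min(P(U <= u), P(U >= u))), matching the standard
    doubled-tail convention.
    """
    cdf = exact_u_cdf(n1, n2)
    u = np.atleast_1d(np.asarray(u1)).astype(int)
    lower = cdf[u]
    upper = np.where(u > 0, 1.0 - cdf[u - 1], 1.0)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def asymptotic_two_sided_p(u1, n1: int, n2: int, tie_term: float) -> np.ndarray:
    """Normal approximation with tie and continuity corrections.

    ``tie_term`` is sum(t^3 - t) over tie groups of the pooled sample.
    """
    u = np.atleast_1d(np.asarray(u1, dtype=float))
    n = n1 + n2
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all pooled values tied
        return np.ones_like(u)
    z = np.maximum(np.abs(u - mu) - 0.5, 0.0) / np.sqrt(var)
    return np.minimum(1.0, 2.0 * norm.sf(z))


def tie_correction_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def mwu_two_sided(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(U1, two-sided p) for samples ``x`` vs ``y``.

    U1 counts (x_i > y_j) pairs with half credit for ties, i.e. the
    rank-sum form U1 = R1 - n1(n1+1)/2 on the pooled average ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    tie_term = tie_correction_term(pooled)
    if n1 + n2 <= EXACT_MAX_N and tie_term == 0:
        p = float(exact_two_sided_p(int(round(u1)), n1, n2)[0])
    else:
        p = float(asymptotic_two_sided_p(u1, n1, n2, tie_term)[0])
    return float(u1), p
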