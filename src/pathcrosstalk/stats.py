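"""Shared statistical primitives.

These are the small building blocks used by the candidate-gene and
subpathway stages: vectorised Welch t-tests, Benjamini-Hochberg step-up
adjustment, the upper-tail hypergeometric enrichment probability and the
add-one-smoothed empirical permutation p-value.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = [
    "bh_adjust",
    "hypergeom_upper_tail",
    "welch_t_test",
    "permutation_pvalue",
]

#: standard errors below this floor are clamped so a zero-variance gene
#: yields a huge-but-finite t statistic rather than inf/nan
VAR_FLOOR = 1e-8


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Parameters
    ----------
    pvals : array-like of float in [0, 1]

    Returns
    -------
    ndarray of adjusted p-values, clipped at 1, in the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


def hypergeom_upper_tail(k: int, K: int, m: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K successes, m draws).

    Used to score candidate-gene enrichment of a subpathway: ``k``
    candidates among its ``m`` members, against ``K`` candidates in a
    background of ``N`` genes.
    """
    for name, v in (("k", k), ("K", K), ("m", m), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
    if K > N or m > N:
        raise ValueError(f"K={K} and m={m} must not exceed N={N}")
    if k > min(K, m):
        raise ValueError(f"k={k} exceeds min(K={K}, m={m})")
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, m))


def welch_t_test(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided Welch t-test between two sample groups.

    ``x`` and ``y`` are (genes x samples) arrays for the two classes.
    Returns ``(t, p)``. Rows where both groups are essentially constant
    get their standard error clamped to ``VAR_FLOOR`` instead of
    producing non-finite statistics.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.shape[1], y.shape[1]
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least two samples")
    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx, vy = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    sx2, sy2 = vx / nx, vy / ny
    se = np.sqrt(sx2 + sy2)
    se = np.maximum(se, VAR_FLOOR)
    t = (mx - my) / se
    # Welch-Satterthwaite df; degenerate rows fall back to nx+ny-2
    denom = sx2**2 / (nx - 1) + sy2**2 / (ny - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = (sx2 + sy2) ** 2 / denom
    df = np.where(np.isfinite(df) & (df > 0), df, nx + ny - 2)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return t, np.minimum(p, 1.0)


def permutation_pvalue(observed: float, null_scores, raw: bool = False) -> float:
    """Empirical p-value of ``observed`` against a permutation null.

    The default add-one smoothing ``(b + 1) / (N + 1)`` — with ``b`` the
    number of null scores >= observed — never returns 0, which keeps BH
    ranking well defined. ``raw=True`` restores the literal ``b / N``
    count.
    """
    null = np.asarray(null_scores, dtype=float)
    if null.size == 0:
        raise ValueError("null_scores must be nonempty")
    b = int(np.count_nonzero(null >= observed))
    if raw:
        return b / null.size
    return (b + 1) / (null.size + 1)
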