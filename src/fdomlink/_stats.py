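"""Shared statistical primitives: rank correlation, FDR, binomial intervals."""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from scipy import stats as sps

from .errors import FdomlinkError

__all__ = ["spearman_rho_p", "bh_qvalues", "wilson_interval"]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise FdomlinkError("correlation undefined for constant input")
    return float((xc @ yc) / denom)


@lru_cache(maxsize=8)
def _perm_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def spearman_rho_p(x, y, exact_below: int = 10) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive average ranks. For ``n >= exact_below`` the p-value uses the
    t approximation; below that the full permutation distribution of the rank
    statistic is enumerated (exact even under ties).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 3:
        raise FdomlinkError("spearman requires two equal-length vectors, n >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _pearson(rx, ry)
    if n >= exact_below:
        # t approximation, matching scipy's default
        if abs(rho) >= 1.0:
            return rho, 0.0
        t = rho * np.sqrt((n - 2) / (1 - rho * rho))
        p = 2 * sps.t.sf(abs(t), df=n - 2)
        return rho, float(min(p, 1.0))
    perms = _perm_matrix(n)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc @ rxc) * (ryc @ ryc))
    rho_perm = (rxc[perms] @ ryc) / denom
    p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    return rho, p


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values; guarantees q >= p elementwise."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def wilson_interval(p_hat: float, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise FdomlinkError("wilson interval requires n > 0")
    denom = 1 + z * z / n
    center = (p_hat + z * z / (2 * n)) / denom
    half = z * np.sqrt(p_hat * (1 - p_hat) / n + z * z / (4 * n * n)) / denom
    return max(0.0, center - half), min(1.0, center + half)
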