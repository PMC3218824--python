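"""Exact discrete tests shared by the allelic and ASM modules.

The two-sided binomial p-value follows the minimum-likelihood convention:
the sum of the probabilities of all outcomes no more probable than the
observed one. Degenerate success probabilities (0 or 1) are point masses
and handled exactly.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["exact_binom_two_sided", "hypergeom_upper_tail", "bh_threshold", "bh_reject"]

_TIE_REL = 1e-9  # relative guard so float ties (e.g. pmf(k) vs pmf(n-k)) count


def exact_binom_two_sided(k: int, n: int, p: float) -> float:
    """Two-sided exact binomial p-value of ``k`` successes in ``n`` trials
    under success probability ``p`` (minlike convention)."""
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    if n == 0:
        raise ValueError("n must be positive")
    if p <= 0.0:
        return 1.0 if k == 0 else 0.0
    if p >= 1.0:
        return 1.0 if k == n else 0.0
    pmf = stats.binom.pmf(np.arange(n + 1), n, p)
    return float(min(1.0, pmf[pmf <= pmf[k] * (1 + _TIE_REL)].sum()))


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(population N, successes K, draws n)."""
    if min(N, K, n, k) < 0 or K > N or n > N:
        raise ValueError("invalid hypergeometric parameters")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_threshold(p_values, q: float) -> float:
    """Benjamini-Hochberg: the largest p-value passing FDR level ``q``
    (0.0 when nothing passes)."""
    p = np.sort(np.asarray(p_values, dtype=float))
    m = p.size
    if m == 0:
        return 0.0
    crit = q * np.arange(1, m + 1) / m
    passing = np.flatnonzero(p <= crit)
    return float(p[passing[-1]]) if passing.size else 0.0


def bh_reject(p_values, q: float) -> np.ndarray:
    thr = bh_threshold(p_values, q)
    return np.asarray(p_values, dtype=float) <= thr if thr > 0 else np.zeros(
        len(p_values), dtype=bool
    )
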