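"""Exact small-sample statistics shared across the pipeline.

Hypergeometric tails model overlap enrichment as an urn: a population of N
exchangeable units (TE copies, scored cytosines, genome bp) of which K are
"successes", n are drawn, and k successes are observed in the draw. Both
tails are inclusive. N can reach genome scale (~4e8 bp), which the
log-space implementation underneath handles without overflow.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as _st

from .errors import UsageError


def _check(k: int, N: int, K: int, n: int) -> None:
    if not (0 <= K <= N):
        raise UsageError(f"require 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise UsageError(f"require 0 <= n <= N, got n={n}, N={N}")
    if not (max(0, n + K - N) <= k <= min(n, K)):
        raise UsageError(
            f"observed k={k} outside support [{max(0, n + K - N)}, {min(n, K)}] "
            f"for N={N}, K={K}, n={n}"
        )


def hypergeom_upper(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), inclusive upper tail."""
    _check(k, N, K, n)
    return float(min(1.0, max(0.0, _st.hypergeom.sf(k - 1, N, K, n))))


def hypergeom_lower(k: int, N: int, K: int, n: int) -> float:
    """P(X <= k), inclusive lower tail. Complements hypergeom_upper(k+1)."""
    _check(k, N, K, n)
    return float(min(1.0, max(0.0, _st.hypergeom.cdf(k, N, K, n))))


def t_mean_ci(values, level: float = 0.95) -> tuple[float, float]:
    """Two-sided t confidence interval for the mean of ``values``.

    mean +/- t(1-(1-level)/2, n-1) * sd / sqrt(n) with sample sd (n-1).
    Zero variance yields a zero-width interval at the mean.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise UsageError(f"need >= 2 values for a t interval, got {v.size}")
    if not (0.0 < level < 1.0):
        raise UsageError(f"level must be in (0, 1), got {level}")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0.0:
        return (mean, mean)
    half = float(_st.t.ppf(1.0 - (1.0 - level) / 2.0, v.size - 1)) * sd / math.sqrt(v.size)
    return (mean - half, mean + half)


def empirical_interval(values, level: float = 0.95) -> tuple[float, float]:
    """Inclusive empirical percentile interval (e.g. 2.5/97.5 for level 0.95)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise UsageError(f"need >= 2 values, got {v.size}")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(v, [alpha, 1.0 - alpha])
    return (float(lo), float(hi))
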