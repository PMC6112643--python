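"""Sample entropy of band-limited uterine signal segments.

Sample entropy SE(m, r) estimates the regularity of a time series: the
negative log of the conditional probability that two sequences matching for
``m - 1`` points (within Chebyshev tolerance ``r``) also match for ``m``
points.  A low SE flags the presence of a periodic physiological mechanism
(e.g., the maternal heart rate in band B1); a high SE flags its absence.

Conventions
-----------
* Segments are standardized to zero mean and unit variance before matching,
  so ``r`` (default 0.15) acts as a fraction of the segment's SD and the
  statistic is invariant to amplifier gain.
* Templates of length ``m`` and ``m - 1`` are both taken at the same
  ``N - m`` starting positions, so the regular branch satisfies
  ``c_m <= c_{m-1}`` and SE >= 0.
* When either count is zero the fallback ``-log((N-m)/(N-m-1))`` is
  returned verbatim.  Note this value is slightly *negative* (the argument
  exceeds 1); it is kept as published rather than silently corrected.
* Matches are counted as ordered pairs; only the ratio enters SE.

A brute-force O(N² m) counter is provided alongside the vectorized
implementation and serves as its oracle in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["SampleEntropyParams", "MatchCounts", "count_matches",
           "count_matches_bruteforce", "sample_entropy"]


@dataclass(frozen=True)
class SampleEntropyParams:
    """Pattern length ``m`` and tolerance ``r`` (fraction of segment SD)."""

    m: int = 3
    r: float = 0.15

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"pattern length m must be >= 1, got {self.m}")
        if self.r <= 0:
            raise ValueError(f"tolerance r must be positive, got {self.r}")


@dataclass(frozen=True)
class MatchCounts:
    """Ordered template-pair match counts at lengths m and m-1."""

    c_m: int
    c_m_minus_1: int
    N: int


def count_matches_bruteforce(y: np.ndarray, m: int, r: float) -> MatchCounts:
    """Reference double-loop counter (kept deliberately naive)."""
    y = np.asarray(y, dtype=np.float64)
    N = y.size
    if N <= m + 1:
        raise ValueError(f"need N > m + 1, got N={N}, m={m}")
    P = N - m
    c_m = 0
    c_m1 = 0
    for l in range(P):
        for ns in range(P):
            if ns == l:
                continue
            d = 0.0
            for i in range(m):
                d = max(d, abs(y[l + i] - y[ns + i]))
                if i == m - 2 and d <= r:
                    c_m1 += 1
            if d <= r:
                c_m += 1
            if m == 1:
                c_m1 += 1          # zero-length templates always match
    return MatchCounts(c_m, c_m1, N)


try:
    from numba import njit as _njit

    @_njit(cache=False)
    def _count_pairs_jit(y, m, r):          # pragma: no cover - compiled
        N = y.size
        P = N - m
        c_m = 0
        c_m1 = 0
        for l in range(P):
            for ns in range(P):
                if ns == l:
                    continue
                d = 0.0
                ok = True
                for i in range(m - 1):
                    diff = abs(y[l + i] - y[ns + i])
                    if diff > d:
                        d = diff
                    if d > r:
                        ok = False
                        break
                if not ok:
                    continue
                c_m1 += 1
                if abs(y[l + m - 1] - y[ns + m - 1]) <= r and d <= r:
                    c_m += 1
        return c_m, c_m1

    _HAVE_NUMBA = True
except ImportError:                          # pragma: no cover
    _HAVE_NUMBA = False


def count_matches(y: np.ndarray, m: int, r: float) -> MatchCounts:
    """Optimized ordered-pair match counter (equals the brute-force one).

    Uses a compiled early-abort scan when numba is importable, otherwise a
    vectorized numpy path; both agree exactly with
    :func:`count_matches_bruteforce`.
    """
    y = np.ascontiguousarray(y, dtype=np.float64)
    N = y.size
    if N <= m + 1:
        raise ValueError(f"need N > m + 1, got N={N}, m={m}")
    if _HAVE_NUMBA:
        c_m, c_m1 = _count_pairs_jit(y, m, r)
        return MatchCounts(int(c_m), int(c_m1), N)
    return _count_matches_numpy(y, m, r)


def _count_matches_numpy(y: np.ndarray, m: int, r: float) -> MatchCounts:
    N = y.size
    P = N - m
    within = np.abs(y[:P, None] - y[None, :P]) <= r
    run = within.copy()
    for i in range(1, m):
        run &= np.abs(y[i:i + P, None] - y[None, i:i + P]) <= r
        if i == m - 2:
            c_m1 = int(run.sum()) - P          # exclude the diagonal
    if m == 1:
        c_m1 = P * (P - 1)
    elif m == 2:
        c_m1 = int(within.sum()) - P
    c_m = int(run.sum()) - P
    return MatchCounts(c_m, c_m1, N)


def sample_entropy(y: np.ndarray,
                   params: SampleEntropyParams = SampleEntropyParams(),
                   *, counter=count_matches) -> float:
    """Sample entropy of ``y`` after per-segment standardization (nats).

    A zero-variance segment is the all-match case and returns 0.  When no
    matches exist at either length, the published fallback
    ``-log((N-m)/(N-m-1))`` is returned.
    """
    y = np.asarray(y, dtype=np.float64)
    N = y.size
    m = params.m
    if N <= m + 1:
        raise ValueError(f"need N > m + 1, got N={N}, m={m}")
    sd = y.std()
    if sd == 0:
        return 0.0
    z = (y - y.mean()) / sd
    counts = counter(z, m, params.r)
    if counts.c_m != 0 and counts.c_m_minus_1 != 0:
        return -math.log(counts.c_m / counts.c_m_minus_1)
    return -math.log((N - m) / (N - m - 1))
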