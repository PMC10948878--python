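"""Statistical tests shared by every pipeline stage.

All tests are two-sided and deterministic. Exact enumeration is used at
small sample sizes; large samples fall back to normal approximations with
tie and continuity corrections. Implementations are intentionally
self-contained so they can be validated against brute-force oracles.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "TestResult",
    "fisher_exact_2x2",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "benjamini_hochberg",
]

# relative tolerance guarding float ties in the probability-mass rule
_FISHER_RTOL = 1e-7


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided hypothesis test."""

    statistic: float
    p_value: float
    method: str
    sided: str = "two-sided"
    n_per_group: tuple = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "p": float(self.p_value),
            "method": self.method,
        }


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    The two-sided p-value follows the probability-mass rule: the sum of
    hypergeometric probabilities (margins fixed) of every table at most as
    probable as the observed one, with a relative tolerance of 1e-7 to
    guard float ties. Computed in exact integer arithmetic.
    """
    counts = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in counts):
        raise ValueError(f"counts must be nonnegative integers, got {counts}")
    a, b, c, d = (int(x) for x in counts)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        raise ValueError("empty table")

    # support of the hypergeometric distribution for the top-left cell
    k_lo = max(0, c1 - r2)
    k_hi = min(r1, c1)
    # unnormalized point masses: C(r1, k) * C(r2, c1-k)
    num_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = 0
    kept = 0
    # integer-exact version of num_k <= num_obs * (1 + rtol)
    scale = 10**9
    thresh = num_obs * (scale + int(_FISHER_RTOL * scale))
    for k in range(k_lo, k_hi + 1):
        num_k = math.comb(r1, k) * math.comb(r2, c1 - k)
        total += num_k
        if num_k * scale <= thresh:
            kept += num_k
    p = float(Fraction(kept, total))
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    return TestResult(odds, min(p, 1.0), "fisher_exact", n_per_group=(r1, r2))


def _mwu_exact_sf(n1: int, n2: int) -> np.ndarray:
    """Null distribution counts of U for sample sizes n1, n2 (no ties).

    Returns an array ``cnt`` where ``cnt[u]`` is the number of rank
    arrangements giving U == u; U ranges over 0..n1*n2.
    """
    # classic recursion: f(n1, n2, u) counts partitions
    max_u = n1 * n2
    cnt = np.zeros(max_u + 1, dtype=float)
    for combo in itertools.combinations(range(n1 + n2), n1):
        # U = number of (x, y) pairs with rank(x) > rank(y)
        u = sum(combo) - n1 * (n1 - 1) // 2
        cnt[u] += 1
    return cnt


def mann_whitney_u(x, y, exact_max_n: int = 8) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration of the rank distribution when both samples have at
    most ``exact_max_n`` observations and the data contain no ties;
    otherwise a normal approximation with tie correction and continuity
    correction is used. The reported statistic is U for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2
    u2 = n1 * n2 - u1

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if n1 <= exact_max_n and n2 <= exact_max_n and not has_ties:
        cnt = _mwu_exact_sf(n1, n2)
        total = cnt.sum()
        u_min = min(u1, u2)
        p = 2.0 * cnt[: int(round(u_min)) + 1].sum() / total
        return TestResult(u1, min(p, 1.0), "mann_whitney_exact", n_per_group=(n1, n2))

    n = n1 + n2
    mean = n1 * n2 / 2.0
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all values identical
        return TestResult(u1, 1.0, "mann_whitney_normal", n_per_group=(n1, n2))
    diff = u1 - mean
    # continuity correction toward the mean
    cc = 0.5 if diff != 0 else 0.0
    z = (abs(diff) - cc) / math.sqrt(var)
    z = max(z, 0.0)
    p = 2.0 * norm.sf(z)
    return TestResult(u1, min(p, 1.0), "mann_whitney_normal", n_per_group=(n1, n2))


def wilcoxon_signed_rank(diffs, exact_max_n: int = 12) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon convention). Exact enumeration
    over all 2^n sign assignments (using the observed tied ranks) for
    n <= ``exact_max_n``; normal approximation with tie and continuity
    corrections otherwise. The statistic is W+, the positive-rank sum.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()

    if n <= exact_max_n:
        # distribution of W+ under random signs, honoring tied ranks
        sums = np.zeros(1)
        for r in ranks:
            sums = np.concatenate([sums, sums + r])
        total = len(sums)
        p_lo = (sums <= w_pos + 1e-12).sum() / total
        p_hi = (sums >= w_pos - 1e-12).sum() / total
        p = 2.0 * min(p_lo, p_hi)
        return TestResult(w_pos, min(p, 1.0), "wilcoxon_exact", n_per_group=(n,))

    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    diff = w_pos - mean
    cc = 0.5 if diff != 0 else 0.0
    z = max(abs(diff) - cc, 0.0) / math.sqrt(var)
    p = 2.0 * norm.sf(z)
    return TestResult(w_pos, min(p, 1.0), "wilcoxon_normal", n_per_group=(n,))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted q-values, original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downward
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
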