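"""Statistical primitives shared by every pipeline stage.

All tests of association and enrichment in the pipeline reduce to four
primitives: Pearson correlation with a t-based p-value, Benjamini–Hochberg
FDR adjustment, the Wilcoxon rank-sum (Mann–Whitney) test, and the
hypergeometric upper tail.  They are implemented here in full (scipy is used
only for distribution functions) so each can be verified against a
brute-force oracle at small n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp, ndtr
from scipy.stats import rankdata, t as t_dist

__all__ = [
    "TestResult",
    "ConstantInputError",
    "pearson_with_p",
    "bh_adjust",
    "wilcoxon_rank_sum",
    "hypergeom_tail",
    "empirical_cdf",
    "ECDF",
    "fold_change_ddct",
]


class ConstantInputError(ValueError):
    """Raised when a correlation is requested for a zero-variance vector."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample test."""

    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with a two-sided t-approximation p-value.

    The p-value comes from t = r·sqrt(n-2)/sqrt(1-r²) on n-2 degrees of
    freedom; |r| = 1 maps to p = 0.  A permutation p-value would be
    prohibitive for all-pairs network construction, so the t approximation
    is used throughout.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = float(np.sqrt(np.sum(xd * xd)))
    sy = float(np.sqrt(np.sum(yd * yd)))
    if sx == 0.0 or sy == 0.0:
        raise ConstantInputError("correlation undefined for a constant vector")
    r = float(np.dot(xd, yd) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-12:  # exact collinearity up to float noise
        return math.copysign(1.0, r), 0.0
    tstat = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    p = 2.0 * float(t_dist.sf(abs(tstat), n - 2))
    return r, min(1.0, p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order.

    q_(i) = min_{j>=i}( p_(j) * m / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


@lru_cache(maxsize=256)
def _ranksum_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Counts of subsets of {1..n1+n2} of size n1 by rank sum.

    Index w of the returned tuple is the number of size-n1 subsets whose
    rank sum equals w (classic Mann–Whitney counting recursion).
    """
    n = n1 + n2
    max_sum = n1 * n
    # dp[k][s]: number of k-subsets of the ranks seen so far with sum s
    dp = [[0] * (max_sum + 1) for _ in range(n1 + 1)]
    dp[0][0] = 1
    for rank in range(1, n + 1):
        for k in range(min(rank, n1), 0, -1):
            row, prev = dp[k], dp[k - 1]
            for s in range(max_sum, rank - 1, -1):
                c = prev[s - rank]
                if c:
                    row[s] += c
    return tuple(dp[n1])


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> TestResult:
    """Two-sided Wilcoxon rank-sum test.

    mode="exact" enumerates the full null distribution of the rank sum over
    all C(n1+n2, n1) assignments (valid without ties); mode="normal_approx"
    uses the normal approximation with mid-rank tie correction and a 0.5
    continuity correction; mode="auto" picks exact when both samples have
    at most 10 observations and there are no ties.

    The two-sided p is min(1, 2·min(P(W ≤ w), P(W ≥ w))).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = int(x.size), int(y.size)
    n = n1 + n2
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)  # mid-ranks on ties
    w = float(ranks[:n1].sum())
    has_ties = np.unique(combined).size < n

    if mode == "auto":
        mode = "exact" if (n1 <= 10 and n2 <= 10 and not has_ties) else "normal_approx"
    if mode == "exact":
        if has_ties:
            raise ValueError("exact mode requires tie-free data")
        counts = _ranksum_counts(n1, n2)
        total = math.comb(n, n1)
        wi = int(round(w))
        p_le = sum(counts[: wi + 1]) / total
        p_ge = sum(counts[wi:]) / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(w, p, "wilcoxon-exact", n1, n2)
    if mode != "normal_approx":
        raise ValueError(f"unknown mode: {mode!r}")

    mu = n1 * (n + 1) / 2.0
    # tie correction on the rank variance
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return TestResult(w, 1.0, "wilcoxon-normal", n1, n2)
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * float(1.0 - ndtr(z)))
    return TestResult(w, p, "wilcoxon-normal", n1, n2)


def _log_comb(a: float, b: float) -> float:
    return float(gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1))


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n), in log-space.

    N is the universe size, K the annotated (marked) count, n the query
    (draw) size and k the observed overlap.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if K > N or n > N:
        raise ValueError("K and n must not exceed N")
    if k > min(K, n):
        raise ValueError("overlap k cannot exceed min(K, n)")
    if k == 0:
        return 1.0
    lo_denom = _log_comb(N, n)
    logs = [
        _log_comb(K, i) + _log_comb(N - K, n - i) - lo_denom
        for i in range(k, min(K, n) + 1)
        if n - i <= N - K
    ]
    if not logs:
        return 0.0
    return min(1.0, float(np.exp(logsumexp(logs))))


class ECDF:
    """Right-continuous empirical CDF as a step function."""

    def __init__(self, values: Sequence[float]):
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError("empirical CDF of an empty sample is undefined")
        v = np.sort(v)
        self.support, counts = np.unique(v, return_counts=True)
        self.fractions = np.cumsum(counts) / v.size

    def __call__(self, x) -> np.ndarray:
        idx = np.searchsorted(self.support, np.asarray(x, dtype=float), side="right")
        padded = np.concatenate([[0.0], self.fractions])
        return padded[idx]


def empirical_cdf(values: Sequence[float]) -> ECDF:
    """Empirical CDF of a sample; final value is 1 by construction."""
    return ECDF(values)


def fold_change_ddct(
    ct_target: Mapping[str, float],
    ct_reference: Mapping[str, float],
    control_ids: Sequence[str],
) -> dict[str, float]:
    """Relative expression by the 2^−ΔΔCt method.

    ΔCt_s = Ct_target,s − Ct_reference,s, normalising the target transcript
    to an internal reference (e.g. GAPDH); ΔΔCt_s subtracts the mean ΔCt of
    the control group; the fold change is 2^(−ΔΔCt_s).  By construction the
    geometric mean of the control-group fold changes is 1.
    """
    control_ids = list(control_ids)
    if not control_ids:
        raise ValueError("control_ids must be non-empty")
    samples = list(ct_target)
    for s in samples:
        if s not in ct_reference:
            raise KeyError(f"missing reference Ct for sample {s!r}")
    for s in control_ids:
        if s not in ct_target:
            raise KeyError(f"missing target Ct for control sample {s!r}")
    dct = {s: float(ct_target[s]) - float(ct_reference[s]) for s in samples}
    control_mean = float(np.mean([dct[s] for s in control_ids]))
    return {s: float(2.0 ** -(dct[s] - control_mean)) for s in samples}
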