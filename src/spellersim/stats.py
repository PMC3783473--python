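"""Nonparametric inference for small paired cohorts.

Implements the exact Wilcoxon signed-rank test (full enumeration of sign
assignments for small n), Spearman rank correlation and Spearman partial
rank correlation, with permutation-based two-sided significance
(permuting the raw observations of one variable, 20000 permutations by
default, p with the add-one convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "PairedSample",
    "CorrelationResult",
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "spearman_perm",
    "spearman_partial_perm",
]

EXACT_N_MAX = 15
DEFAULT_N_PERM = 20000


@dataclass(frozen=True)
class PairedSample:
    """Per-subject value pairs for a paired comparison."""

    x: np.ndarray
    y: np.ndarray
    subjects: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be equal-length vectors")
        if len(self.x) < 2:
            raise ValueError("at least 2 pairs required")
        if self.subjects is not None and len(self.subjects) != len(self.x):
            raise ValueError("one subject id per pair required")


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float         # W = min(W+, W-)
    p_value: float
    n_used: int              # pairs remaining after zero-difference removal
    zeros_dropped: int
    method: str              # "exact" or "normal"


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    p_value: float
    n_permutations: int
    undefined: bool = False


def _signed_rank_w(d: np.ndarray) -> tuple[float, float, np.ndarray]:
    """(W+, W-) and the mid-ranks of |d| for nonzero differences."""
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    return w_pos, w_neg, ranks


def _exact_min_w_p(ranks: np.ndarray, w_obs: float) -> float:
    """P(min(W+, W-) <= w_obs) over all 2^n equiprobable sign patterns."""
    n = len(ranks)
    total = ranks.sum()
    # distribution of W+ by dynamic programming over half-rank units
    # (mid-ranks are multiples of 0.5, so double them to stay integral)
    units = np.round(2 * ranks).astype(int)
    span = int(units.sum())
    counts = np.zeros(span + 1, dtype=float)
    counts[0] = 1.0
    for u in units:
        shifted = np.zeros_like(counts)
        shifted[u:] = counts[: span + 1 - u]
        counts = counts + shifted
    w_plus = np.arange(span + 1) / 2.0
    w_min = np.minimum(w_plus, total - w_plus)
    return float(counts[w_min <= w_obs + 1e-12].sum() / 2**n)


def wilcoxon_signed_rank(sample: PairedSample) -> WilcoxonResult:
    """Wilcoxon signed-rank test for a paired difference in location.

    Differences ``d = y - x``; zero differences are dropped (flagged via
    ``zeros_dropped``); |d| is ranked with mid-ranks for ties; the
    statistic is ``W = min(W+, W-)``. For n <= 15 remaining pairs the
    two-sided p is exact — the probability, over all 2^n equiprobable
    sign assignments, that min(W+, W-) is at most the observed W.
    Larger n uses the normal approximation with tie correction.
    """
    d = sample.y - sample.x
    zeros = int((d == 0).sum())
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, zeros, "degenerate")
    w_pos, w_neg, ranks = _signed_rank_w(d)
    w = min(w_pos, w_neg)
    if n <= EXACT_N_MAX:
        p = _exact_min_w_p(ranks, w)
        return WilcoxonResult(w, min(p, 1.0), n, zeros, "exact")
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w - mean + 0.5) / np.sqrt(var)  # continuity-corrected
    from scipy.stats import norm
    p = float(min(1.0, 2.0 * norm.cdf(z)))
    return WilcoxonResult(w, p, n, zeros, "normal")


def _rank_corr(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = rankdata(x), rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_perm(x, y, n_perm: int = DEFAULT_N_PERM,
                  seed: int = 0) -> CorrelationResult:
    """Spearman correlation with permutation-based two-sided significance.

    The coefficient is the Pearson correlation of mid-ranks. The null is
    built by permuting the raw observations of ``y`` ``n_perm`` times;
    ``p = (#{|r_perm| >= |r_obs|} + 1) / (n_perm + 1)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length vectors of length >= 3")
    r = _rank_corr(x, y)
    if np.isnan(r):
        return CorrelationResult(np.nan, np.nan, 0, undefined=True)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        rp = _rank_corr(x, rng.permutation(y))
        if abs(rp) >= abs(r) - 1e-12:
            exceed += 1
    return CorrelationResult(r, (exceed + 1) / (n_perm + 1), n_perm)


def _partial_from_ranks(rx, ry, rz) -> float:
    r_xy = float(np.corrcoef(rx, ry)[0, 1])
    r_xz = float(np.corrcoef(rx, rz)[0, 1])
    r_yz = float(np.corrcoef(ry, rz)[0, 1])
    denom = (1 - r_xz**2) * (1 - r_yz**2)
    if denom <= 0:
        return np.nan
    return (r_xy - r_xz * r_yz) / np.sqrt(denom)


def spearman_partial_perm(x, y, z, n_perm: int = DEFAULT_N_PERM,
                          seed: int = 0) -> CorrelationResult:
    """Spearman partial correlation of x and y controlling for z.

    All three variables are rank-transformed; the partial coefficient is
    ``(r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))``. The
    permutation null permutes the raw ``y`` while the (x, z) pairing is
    kept fixed; two-sided p with the add-one convention. If x or y is
    rank-degenerate with z (|r| = 1) the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1 or len(x) < 4:
        raise ValueError("x, y, z must be equal-length vectors of length >= 4")
    rx, rz = rankdata(x), rankdata(z)
    if rx.std() == 0 or rz.std() == 0 or rankdata(y).std() == 0:
        return CorrelationResult(np.nan, np.nan, 0, undefined=True)
    r = _partial_from_ranks(rx, rankdata(y), rz)
    if np.isnan(r):
        return CorrelationResult(np.nan, np.nan, 0, undefined=True)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        rp = _partial_from_ranks(rx, rankdata(rng.permutation(y)), rz)
        if not np.isnan(rp) and abs(rp) >= abs(r) - 1e-12:
            exceed += 1
    return CorrelationResult(r, (exceed + 1) / (n_perm + 1), n_perm)
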