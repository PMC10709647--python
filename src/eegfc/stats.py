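"""Mass-univariate group statistics: Wilcoxon rank-sum, BH-FDR, Friedman.

The rank-sum test uses midranks for ties, exact enumeration of all group
assignments when the pooled sample has at most EXACT_LIMIT observations,
and otherwise a tie-corrected normal approximation with continuity
correction. Benjamini-Hochberg adjustment is the standard step-up rule
with monotonicity enforcement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

EXACT_LIMIT = 12  # pooled size up to which the tied exact null is enumerated
EXACT_NOTIES_LIMIT = 40  # pooled size for the tie-free exact null (DP counts)


class StatsError(ValueError):
    pass


@lru_cache(maxsize=64)
def _combination_indices(n_a: int, n: int) -> np.ndarray:
    """All C(n, n_a) index subsets assigning n_a of n pooled ranks to group a."""
    return np.array(list(combinations(range(n), n_a)), dtype=np.intp)


@lru_cache(maxsize=64)
def _ranksum_counts(n_a: int, n: int) -> np.ndarray:
    """Number of size-n_a subsets of ranks {1..n} with each possible sum.

    Dynamic-programming table of the exact tie-free rank-sum null;
    index s holds the count of subsets summing to s.
    """
    max_sum = n * (n + 1) // 2
    table = np.zeros((n_a + 1, max_sum + 1))
    table[0, 0] = 1.0
    for rank in range(1, n + 1):
        for k in range(min(rank, n_a), 0, -1):
            table[k, rank:] += table[k - 1, :-rank]
    return table[n_a]


def wilcoxon_ranksum(sample_a: Sequence[float],
                     sample_b: Sequence[float]) -> Tuple[float, float]:
    """Two-tailed Wilcoxon rank-sum test.

    Returns ``(W, p)`` where W is the sum of the midranks of ``sample_a``
    in the pooled sample. The two-tailed p (2 x min tail, capped at 1) is
    exact for tie-free pooled samples up to 40 observations (DP over the
    rank-sum null) and for tied samples up to 12 (full enumeration);
    larger samples use the normal approximation with tie-corrected
    variance and continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("both samples must be non-empty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise StatsError("samples must be finite")
    pooled = np.concatenate([a, b])
    n_a, n = a.size, pooled.size
    ranks = rankdata(pooled)
    w = float(ranks[:n_a].sum())

    has_ties = np.unique(pooled).size < n
    if not has_ties and n <= EXACT_NOTIES_LIMIT:
        counts = _ranksum_counts(n_a, n)
        total = counts.sum()
        w_int = int(round(w))
        p_lo = counts[: w_int + 1].sum() / total
        p_hi = counts[w_int:].sum() / total
        return w, float(min(1.0, 2.0 * min(p_lo, p_hi)))

    if n <= EXACT_LIMIT:
        subsets = _combination_indices(n_a, n)
        dist = ranks[subsets].sum(axis=1)
        p_lo = np.mean(dist <= w + 1e-9)
        p_hi = np.mean(dist >= w - 1e-9)
        return w, float(min(1.0, 2.0 * min(p_lo, p_hi)))

    mean = n_a * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3) - counts).sum())
    n_b = n - n_a
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # every observation tied
        return w, 1.0
    diff = w - mean
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    return w, float(min(1.0, 2.0 * norm.sf(abs(z))))


def benjamini_hochberg(p_values: Sequence[float],
                       q: float = 0.05) -> Tuple[np.ndarray, np.ndarray]:
    """BH step-up FDR adjustment.

    Returns ``(p_adjusted, reject_mask)`` with ``reject = p_adjusted <= q``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise StatsError("p-values must lie in [0, 1]")
    if not (0 < q < 1):
        raise StatsError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted, adjusted <= q


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    df: int
    p_value: float


FRIEDMAN_EXACT_LIMIT = 20_000  # max (k!)^n for exact permutation p


def _friedman_statistic(ranks: np.ndarray, correction: float) -> float:
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * (col_sums ** 2).sum() - 3.0 * n * (k + 1)
    return max(stat / correction, 0.0)


def friedman_test(data: np.ndarray) -> FriedmanResult:
    """Friedman chi-square test on an (n blocks x k conditions) layout.

    Within-block midranks and the tie-corrected statistic with df = k - 1.
    When the within-block permutation space (k!)^n is small the p-value is
    exact (brute-force over all rank assignments); otherwise the chi-square
    approximation is used. Perfect concordance gives chi2 = n (k - 1);
    constant data gives chi2 = 0, p = 1.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise StatsError("data must be 2-D (blocks x conditions)")
    n, k = data.shape
    if n < 2 or k < 2:
        raise StatsError(f"need >= 2 blocks and >= 2 conditions, got {data.shape}")
    if not np.isfinite(data).all():
        raise StatsError("missing or non-finite cells are not allowed")
    ranks = np.apply_along_axis(rankdata, 1, data)

    tie_sum = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(((counts ** 3) - counts).sum())
    correction = 1.0 - tie_sum / (n * k * (k ** 2 - 1))
    if correction <= 0:
        return FriedmanResult(0.0, k - 1, 1.0)
    stat = _friedman_statistic(ranks, correction)

    if math.factorial(k) ** n <= FRIEDMAN_EXACT_LIMIT:
        from itertools import permutations, product
        perms = list(permutations(range(k)))
        block_variants = [[row[list(p)] for p in perms] for row in ranks]
        null = np.array([
            _friedman_statistic(np.vstack(combo), correction)
            for combo in product(*block_variants)])
        p = float(np.mean(null >= stat - 1e-12))
        return FriedmanResult(float(stat), k - 1, p)
    return FriedmanResult(float(stat), k - 1, float(chi2.sf(stat, k - 1)))


def friedman_channel_effect(values: np.ndarray) -> FriedmanResult:
    """Channel effect: subjects as blocks, channels as conditions (df = k-1)."""
    return friedman_test(values)


def friedman_group_effect(values_a: np.ndarray,
                          values_b: np.ndarray) -> FriedmanResult:
    """Group effect (df = 1) exploiting the cohort's pairwise matching.

    Subjects are matched by index across groups; every (matched pair,
    channel) combination forms one block with the two groups as conditions.
    """
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    if a.shape != b.shape:
        raise StatsError("matched groups must have identical layouts")
    return friedman_test(np.column_stack([a.reshape(-1), b.reshape(-1)]))


@dataclass
class StatResult:
    """Aligned per-feature mass-univariate test results."""

    feature_names: List[str]
    statistics: np.ndarray
    p_values: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray
    direction: np.ndarray  # +1: group A median larger, -1: smaller, 0: tie
    q: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.feature_names,
            "statistic": self.statistics,
            "p": self.p_values,
            "p_adj": self.p_adjusted,
            "significant": self.significant,
            "direction": self.direction,
        }).set_index("feature")


def mass_univariate(features: pd.DataFrame, labels: Sequence[str],
                    group_a: str, q: float = 0.05) -> StatResult:
    """One two-tailed rank-sum test per feature column, BH over the family.

    ``group_a`` names the positive group; direction +1 means its median is
    larger. BH adjustment is applied across all columns of ``features``.
    """
    labels = np.asarray(labels)
    mask_a = labels == group_a
    mask_b = ~mask_a
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise StatsError("each group needs at least 2 subjects")
    names = list(features.columns)
    stats = np.empty(len(names))
    pvals = np.empty(len(names))
    direction = np.zeros(len(names), dtype=int)
    x = features.to_numpy(dtype=float)
    for j in range(len(names)):
        a, b = x[mask_a, j], x[mask_b, j]
        stats[j], pvals[j] = wilcoxon_ranksum(a, b)
        diff = np.median(a) - np.median(b)
        direction[j] = 0 if diff == 0 else (1 if diff > 0 else -1)
    p_adj, reject = benjamini_hochberg(pvals, q)
    return StatResult(names, stats, pvals, p_adj, reject, direction, q)
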