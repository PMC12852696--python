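"""Small-sample statistics used throughout the toolkit.

Comparisons across embryos involve very few observations (typically 3-7
embryos per condition), so the Mann-Whitney test is computed exactly by
enumeration in that regime rather than by normal approximation.  Contingency
tables of division modes are compared with an uncorrected Pearson chi-square
(df = 2 omnibus convention).  Multiple testing uses Benjamini-Hochberg.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "mann_whitney",
    "chi_square_modes",
    "bh_adjust",
    "MannWhitneyResult",
    "ChiSquareResult",
    "goodman_multinomial_ci",
]

#: group sizes up to which the exact (enumerated) null distribution is used
EXACT_MAX_N = 10


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p_two_sided: float
    method: str  # "exact" or "asymptotic"


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    expected: np.ndarray
    collapsed: bool = False


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of sample x versus y, counting ties as 1/2."""
    diff = x[:, None] - y[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    For group sizes <= ``EXACT_MAX_N`` the p-value is exact: the U statistic
    is evaluated under every C(n+m, n) relabeling of the pooled values (this
    handles ties without a continuity fudge) and the two-sided p is
    ``min(1, 2 * min(P(U <= u), P(U >= u)))``.  Larger samples use the normal
    approximation with tie correction.

    All values tied yields p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    if np.all(np.concatenate([x, y]) == np.concatenate([x, y])[0]):
        return MannWhitneyResult(U=x.size * y.size / 2.0, p_two_sided=1.0, method="degenerate")
    u_obs = _u_statistic(x, y)
    n, m = x.size, y.size
    if max(n, m) <= EXACT_MAX_N:
        pooled = np.concatenate([x, y])
        idx = range(n + m)
        n_le = n_ge = total = 0
        for comb in itertools.combinations(idx, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(comb)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if u <= u_obs + 1e-12:
                n_le += 1
            if u >= u_obs - 1e-12:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le, n_ge) / total)
        return MannWhitneyResult(U=u_obs, p_two_sided=p, method="exact")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(U=float(res.statistic), p_two_sided=float(res.pvalue), method="asymptotic")


def chi_square_modes(counts_a, counts_b) -> ChiSquareResult:
    """Pearson chi-square on a 2 x k table of category counts (no Yates).

    ``counts_a``/``counts_b`` are per-category counts (e.g. n_PP, n_PN, n_NN)
    for the two conditions.  A category empty in both rows is collapsed out
    (with a warning), reducing the degrees of freedom accordingly.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("expected two equal-length 1-d count vectors")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    table = np.vstack([a, b])
    keep = table.sum(axis=0) > 0
    collapsed = bool(np.any(~keep))
    if collapsed:
        warnings.warn("category empty in both conditions: collapsed out of the table")
        table = table[:, keep]
    if table.shape[1] < 2:
        raise ValueError("need at least two non-empty categories")
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    if np.any(row == 0):
        raise ValueError("a condition has zero total count")
    expected = row @ col / table.sum()
    if np.any(expected < 5):
        warnings.warn("expected count < 5 in at least one cell; chi-square approximation is weak")
    chi2 = float(np.sum((table - expected) ** 2 / expected))
    df = table.shape[1] - 1
    p = float(sps.chi2.sf(chi2, df))
    return ChiSquareResult(chi2=chi2, df=df, p=p, expected=expected, collapsed=collapsed)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [p, 1])."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d p-value vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def goodman_multinomial_ci(counts, alpha: float = 0.05):
    """Goodman (1965) simultaneous confidence intervals for multinomial proportions.

    Returns an array of (low, high) per category with simultaneous coverage
    ~ 1 - alpha, based on the chi-square(1, 1 - alpha/k) quantile.
    """
    c = np.asarray(counts, dtype=float)
    n = c.sum()
    k = c.size
    if n <= 0:
        raise ValueError("empty multinomial sample")
    q = sps.chi2.ppf(1 - alpha / k, 1)
    half = np.sqrt(q * (q + 4 * c * (n - c) / n))
    low = (q + 2 * c - half) / (2 * (n + q))
    high = (q + 2 * c + half) / (2 * (n + q))
    return np.clip(np.column_stack([low, high]), 0.0, 1.0)
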