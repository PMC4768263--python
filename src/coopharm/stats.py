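"""Statistical primitives: Mann-Whitney U, Pearson correlation, BH adjustment.

These three are the whole statistical surface the discovery method needs:
the U-test drives tree splitting, Pearson correlation links node-conditional
expression to sensitivity, and Benjamini-Hochberg controls the FDR of the
per-node correlation screens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["RankTestResult", "CorrelationResult",
           "mann_whitney_u", "pearson", "bh_adjust"]

#: group-size ceiling below which the exact U distribution is used (no ties)
DEFAULT_EXACT_MAX_N = 8


@dataclass(frozen=True)
class RankTestResult:
    """Two-sided Mann-Whitney U-test outcome; U is reported for group A."""

    u_statistic: float
    p_value: float
    n_altered: int
    n_wildtype: int
    method: str  # "exact" | "normal_approximation"


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with its two-sided t-based p-value.

    ``degenerate`` flags zero-variance input, for which r is undefined
    (reported as NaN, never silently as 0).
    """

    r: float
    p_value: float
    n: int
    degenerate: bool = False


def mann_whitney_u(group_a, group_b,
                   exact_max_n: int = DEFAULT_EXACT_MAX_N) -> RankTestResult:
    """Two-sided Mann-Whitney U-test of ``group_a`` vs ``group_b``.

    The exact null distribution of U is used when both groups have at most
    ``exact_max_n`` observations and the pooled sample is tie-free; otherwise
    a tie-corrected normal approximation with continuity correction.  Two
    groups with no separation at all (every pooled value identical) give
    p = 1 exactly.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups must contain finite values only")

    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return RankTestResult(a.size * b.size / 2.0, 1.0, a.size, b.size,
                              "normal_approximation")

    tie_free = np.unique(pooled).size == pooled.size
    if a.size <= exact_max_n and b.size <= exact_max_n and tie_free:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        method = "normal_approximation"
    p = float(min(max(res.pvalue, np.nextafter(0.0, 1.0)), 1.0))
    return RankTestResult(float(res.statistic), p, a.size, b.size, method)


def pearson(x, y) -> CorrelationResult:
    """Sample Pearson r with two-sided p from the t transform.

    p is computed from ``t = r * sqrt((n-2) / (1-r^2))`` against a Student-t
    distribution with n-2 degrees of freedom.  Exact (anti)linearity yields
    the smallest representable positive p rather than an exact zero; inputs
    with zero variance yield a flagged degenerate result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    n = x.size
    if n < 3:
        raise ValueError("Pearson correlation requires n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must contain finite values only")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), 1.0, n, degenerate=True)

    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    p = _pearson_p(r, n)
    return CorrelationResult(r, p, n)


def _pearson_p(r: float, n: int) -> float:
    tiny = float(np.nextafter(0.0, 1.0))
    if abs(r) >= 1.0:
        return tiny
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return min(max(p, tiny), 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
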