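"""Method-comparison statistics: Spearman rank correlation, coefficient
of determination, Passing-Bablok regression, and the mean square
percentage error used for input-function validation.

Passing-Bablok regression is the nonparametric method-comparison
estimator of choice when both measurements carry error: the slope is a
shifted median of all pairwise slopes, robust to outliers and
symmetric in the two methods, with rank-based confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MethodComparisonResult",
    "PassingBablokResult",
    "spearman_rho",
    "r_squared",
    "passing_bablok",
    "msep",
    "compare_methods",
]


@dataclass(frozen=True)
class PassingBablokResult:
    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_ci: tuple[float, float]
    n: int

    def __post_init__(self) -> None:
        if not (self.slope_ci[0] <= self.slope <= self.slope_ci[1]):
            raise ValueError("slope estimate outside its confidence interval")


@dataclass(frozen=True)
class MethodComparisonResult:
    """Bundle of the comparison statistics between two Ki estimators."""

    pb_slope: float
    pb_slope_ci: tuple[float, float]
    pb_intercept: float
    pb_intercept_ci: tuple[float, float]
    spearman_rho: float
    r2: float
    n: int


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def r_squared(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation (equals OLS R^2 for a simple regression)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("R^2 undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic ** 2)


def _pairwise_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    n = len(x)
    slopes: list[float] = []
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[j] - x[i]
            dy = y[j] - y[i]
            if dx == 0:
                if dy == 0:
                    continue  # identical points carry no slope information
                slopes.append(np.inf if dy > 0 else -np.inf)
            else:
                s = dy / dx
                if s == -1.0:
                    continue  # convention: slopes of exactly -1 are discarded
                slopes.append(s)
    return np.sort(np.asarray(slopes, dtype=float))


def passing_bablok(
    x: Sequence[float], y: Sequence[float], conf: float = 0.95
) -> PassingBablokResult:
    """Passing-Bablok regression (the original 1983 Part I estimator).

    All N pairwise slopes S_ij are formed (vertical pairs count as
    +/-inf; slopes of exactly -1 are discarded); with K the number of
    slopes below -1, the slope estimate is the K-shifted median of the
    sorted slopes, which makes the estimator invariant to swapping the
    two methods.  Confidence bounds come from the rank indices
    M1 = (N - w)/2 and M2 = N - M1 + 1 with
    w = z_{1-alpha/2} * sqrt(n (n-1) (2n+5) / 18), shifted by K.  The
    intercept is median(y - slope * x), its CI evaluated at the slope
    bounds.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    n = len(x)
    S = _pairwise_slopes(x, y)
    N = len(S)
    if N < 3:
        raise ValueError(f"only {N} finite pairwise slope(s); need >= 3")
    K = int(np.sum(S < -1.0))

    def shifted_median(offset: int) -> float:
        if N % 2 == 1:
            return float(S[(N + 1) // 2 + offset - 1])
        return float(0.5 * (S[N // 2 + offset - 1] + S[N // 2 + offset]))

    slope = shifted_median(K)

    z = stats.norm.ppf(0.5 + conf / 2.0)
    w = z * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    M1 = int(round((N - w) / 2.0))
    M2 = N - M1 + 1
    lo_idx = max(M1 + K, 1)
    hi_idx = min(M2 + K, N)
    slope_lo = float(S[lo_idx - 1])
    slope_hi = float(S[hi_idx - 1])

    intercept = float(np.median(y - slope * x))
    intercept_lo = float(np.median(y - slope_hi * x))
    intercept_hi = float(np.median(y - slope_lo * x))

    return PassingBablokResult(
        slope=slope,
        slope_ci=(slope_lo, slope_hi),
        intercept=intercept,
        intercept_ci=(intercept_lo, intercept_hi),
        n=n,
    )


def msep(reference: Sequence[float], candidate: Sequence[float]) -> float:
    """Mean square percentage error between two curves, in percent:

        MSEP = (100 / n) * sum_k ((ref_k - cand_k) / ref_k)^2
    """
    ref = np.asarray(reference, dtype=float)
    cand = np.asarray(candidate, dtype=float)
    if ref.shape != cand.shape or ref.ndim != 1 or len(ref) < 1:
        raise ValueError("need two equal-length vectors with n >= 1")
    if np.any(ref <= 0):
        raise ValueError("MSEP reference values must be positive")
    rel = (ref - cand) / ref
    return float(100.0 * np.mean(rel**2))


def compare_methods(
    x: Sequence[float], y: Sequence[float], conf: float = 0.95
) -> MethodComparisonResult:
    """Full comparison bundle (Passing-Bablok + Spearman + R^2)."""
    pb = passing_bablok(x, y, conf=conf)
    return MethodComparisonResult(
        pb_slope=pb.slope,
        pb_slope_ci=pb.slope_ci,
        pb_intercept=pb.intercept,
        pb_intercept_ci=pb.intercept_ci,
        spearman_rho=spearman_rho(x, y),
        r2=r_squared(x, y),
        n=pb.n,
    )
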