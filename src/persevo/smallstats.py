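"""Small-sample statistical toolkit.

Spearman rank correlation with exact permutation p-values for small n,
Welch t-tests (one- and two-sample), a variance F-test, and
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConstantInputError, InvalidParameterError

__all__ = [
    "CorrelationTest",
    "TTestResult",
    "spearman_exact",
    "welch_t",
    "var_f_test",
    "bh_adjust",
    "EXACT_N_MAX",
]

#: Largest n for which the exact permutation null is enumerated (8! = 40,320).
EXACT_N_MAX = 8


@dataclass(frozen=True)
class CorrelationTest:
    """Spearman rank-correlation result."""

    rho: float
    p: float
    method: str  # "exact" or "approximate"
    n: int


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def _validate_finite(name: str, a: np.ndarray) -> None:
    if not np.all(np.isfinite(a)):
        raise InvalidParameterError(f"{name} contains non-finite values")


def _spearman_rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom)


def spearman_exact(x, y) -> CorrelationTest:
    """Spearman rank correlation with an exact two-sided p-value for small n.

    For n <= 8 with no ties in either variable, the two-sided p-value is
    P(|rho_perm| >= |rho_obs|) over all n! equally likely rank permutations.
    With ties or larger n the t-approximation is used and ``method`` is set
    to ``"approximate"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 3:
        raise InvalidParameterError("need at least 3 paired observations")
    _validate_finite("x", x)
    _validate_finite("y", y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    has_ties = len(set(rx)) < n or len(set(ry)) < n
    rho = _spearman_rho_from_ranks(rx, ry)

    if has_ties or n > EXACT_N_MAX:
        # t-approximation on n - 2 df (guard the |rho| = 1 boundary)
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
        return CorrelationTest(rho=rho, p=min(1.0, p), method="approximate", n=n)

    # exact enumeration: rho depends only on the relative rank permutation;
    # without ties rho = 1 - 6*sum(d^2)/(n(n^2-1)), vectorized over all n!.
    base = np.arange(1.0, n + 1)
    perms = np.array(list(itertools.permutations(base)))
    d2 = ((perms - base) ** 2).sum(axis=1)
    rho_perm = 1.0 - 6.0 * d2 / (n * (n * n - 1))
    hits = int(np.count_nonzero(np.abs(rho_perm) >= abs(rho) - 1e-12))
    return CorrelationTest(rho=rho, p=hits / len(perms), method="exact", n=n)


def welch_t(x, y=None, mu0: float | None = None) -> TTestResult:
    """Welch's t-test (two-sample) or one-sample t-test against ``mu0``.

    Two-sample mode uses the Welch-Satterthwaite degrees of freedom and
    does not assume equal variances. Exactly one of ``y``/``mu0`` must be
    given. Zero variance in one-sample mode yields a degenerate result
    with p in {0, 1} decided by direct comparison.
    """
    x = np.asarray(x, dtype=float)
    _validate_finite("x", x)
    if (y is None) == (mu0 is None):
        raise InvalidParameterError("provide exactly one of y (two-sample) or mu0 (one-sample)")
    if len(x) < 2:
        raise InvalidParameterError("each sample needs n >= 2")

    if y is not None:
        y = np.asarray(y, dtype=float)
        _validate_finite("y", y)
        if len(y) < 2:
            raise InvalidParameterError("each sample needs n >= 2")
        res = stats.ttest_ind(x, y, equal_var=False)
        return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))

    if np.ptp(x) == 0:
        if x[0] == mu0:
            return TTestResult(t=0.0, df=len(x) - 1.0, p=1.0, degenerate=True)
        sign = math.copysign(1.0, x[0] - mu0)
        return TTestResult(t=sign * math.inf, df=len(x) - 1.0, p=0.0, degenerate=True)
    res = stats.ttest_1samp(x, popmean=mu0)
    return TTestResult(t=float(res.statistic), df=len(x) - 1.0, p=float(res.pvalue))


def var_f_test(x, y) -> TTestResult:
    """Two-sided F-test of equal variances (normal-theory)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InvalidParameterError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vy == 0:
        raise ConstantInputError("F-test undefined: zero variance in y")
    f = vx / vy
    dfx, dfy = len(x) - 1, len(y) - 1
    cdf = stats.f.cdf(f, dfx, dfy)
    p = float(2.0 * min(cdf, 1.0 - cdf))
    return TTestResult(t=float(f), df=float(dfx), p=min(1.0, p))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise InvalidParameterError("p must be a nonempty 1-D array")
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest p down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
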