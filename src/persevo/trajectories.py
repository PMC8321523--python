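"""Persister-fraction estimation and sigmoidal adaptation-trajectory fits.

The adaptation model is a four-parameter logistic on log10 persister
fractions,

    p(t) = L + (U - L) / (1 + exp(-S * (t - lam))),

with steepness ``S`` (rate of adaptation) and midpoint ``lam`` (lag before
adaptation). Fixing (L, U) = (0, 1) recovers the strict two-parameter
normalized form for inputs already mapped onto (0, 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    ConstantInputError,
    FractionAboveOneWarning,
    InvalidParameterError,
    SterileCultureWarning,
    UndefinedInputError,
)
from .smallstats import CorrelationTest, spearman_exact

__all__ = [
    "TrajectoryFit",
    "persister_fraction",
    "log10_fraction_floored",
    "fit_adaptation_sigmoid",
    "adaptation_summary",
]


def persister_fraction(cfu_before: float, cfu_after: float) -> float:
    """Survival fraction cfu_after / cfu_before of a fixed-duration treatment.

    Fractions above 1 (counting noise) are reported as-is with a warning,
    never clamped. ``cfu_after == 0`` returns 0.0 with a sterile-culture
    warning (the detection-limit floor is handled separately, see
    :func:`log10_fraction_floored`).
    """
    if cfu_before <= 0:
        raise UndefinedInputError("cfu_before must be > 0")
    if cfu_after < 0:
        raise InvalidParameterError("cfu_after must be >= 0")
    frac = cfu_after / cfu_before
    if cfu_after == 0:
        warnings.warn("zero survivors: sterile culture", SterileCultureWarning)
    elif frac > 1.0:
        warnings.warn(
            f"survival fraction {frac:.3g} > 1 (after > before)", FractionAboveOneWarning
        )
    return frac


def log10_fraction_floored(cfu_before: float, cfu_after: float) -> tuple[float, bool]:
    """log10 survival fraction with a half-detection-limit floor for zeros.

    Returns ``(value, floored)``; a zero survivor count is replaced by half
    a cell, i.e. log10(0.5 / cfu_before), and flagged.
    """
    if cfu_before <= 0:
        raise UndefinedInputError("cfu_before must be > 0")
    if cfu_after == 0:
        return math.log10(0.5 / cfu_before), True
    return math.log10(cfu_after / cfu_before), False


@dataclass
class TrajectoryFit:
    """Fitted adaptation-curve parameters with diagnostics."""

    S: float
    lam: float
    L: float
    U: float
    rss: float
    converged: bool
    n_points: int
    message: str = ""
    ci: dict[str, tuple[float, float]] | None = field(default=None, repr=False)

    def predict(self, t) -> np.ndarray:
        return _sigmoid(np.asarray(t, dtype=float), self.S, self.lam, self.L, self.U)


def _sigmoid(t: np.ndarray, S: float, lam: float, L: float, U: float) -> np.ndarray:
    # clip the exponent so the grid search never overflows
    z = np.clip(-S * (t - lam), -500.0, 500.0)
    return L + (U - L) / (1.0 + np.exp(z))


def _fit_core(
    t: np.ndarray, p: np.ndarray, fix_asymptotes: tuple[float, float] | None
) -> tuple[np.ndarray, float, bool, str]:
    """Grid-seeded damped least squares; returns (params, rss, ok, message)."""
    if fix_asymptotes is None:
        lo, hi = np.percentile(p, [10, 90])
        if hi <= lo:
            hi = lo + 1e-6
        L0, U0 = float(lo), float(hi)
        free_asym = True
    else:
        L0, U0 = fix_asymptotes
        free_asym = False

    s_grid = np.array([0.2, 0.5, 1.0, 2.0, 5.0])
    lam_grid = np.linspace(t.min(), t.max(), 9)
    best = None
    for s0 in s_grid:
        for lam0 in lam_grid:
            r = p - _sigmoid(t, s0, lam0, L0, U0)
            rss = float(r @ r)
            if best is None or rss < best[0]:
                best = (rss, s0, lam0)
    _, s0, lam0 = best

    if free_asym:
        x0 = np.array([s0, lam0, L0, U0])

        def resid(x):
            return p - _sigmoid(t, *x)
    else:
        x0 = np.array([s0, lam0])

        def resid(x):
            return p - _sigmoid(t, x[0], x[1], L0, U0)

    sol = least_squares(resid, x0, method="lm", max_nfev=500 * len(x0), xtol=1e-12, ftol=1e-12)
    params = (
        sol.x if free_asym else np.array([sol.x[0], sol.x[1], L0, U0])
    )
    # canonical orientation: U >= L (model symmetric under (L,U,S)->(U,L,-S))
    if params[3] < params[2]:
        params = np.array([-params[0], params[1], params[3], params[2]])
    rss = float(2.0 * sol.cost)
    ok = bool(sol.success) and np.all(np.isfinite(params))
    return params, rss, ok, sol.message


def fit_adaptation_sigmoid(
    t,
    p,
    fix_asymptotes: tuple[float, float] | None = None,
    ci: bool = False,
    n_boot: int = 200,
    seed: int | None = None,
) -> TrajectoryFit:
    """Least-squares fit of the adaptation sigmoid to a trajectory.

    Parameters
    ----------
    t, p : array-like
        Cycle numbers (strictly increasing, >= 5 points) and log10 persister
        fractions (or normalized values when ``fix_asymptotes=(0, 1)``).
    fix_asymptotes : (L, U) or None
        Fix the asymptotes — ``(0, 1)`` gives the strict two-parameter
        normalized form; ``None`` (default) fits all four parameters.
    ci : bool
        Compute 95% per-parameter intervals by nonparametric (pairs)
        bootstrap with ``n_boot`` resamples.

    Flat or non-convergent data yield ``converged=False`` with a diagnostic
    message, never a silent answer.
    """
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    if t.shape != p.shape or t.ndim != 1:
        raise InvalidParameterError("t and p must be 1-D of equal length")
    if len(t) < 5:
        raise InvalidParameterError("need at least 5 points")
    if np.any(np.diff(t) <= 0):
        raise InvalidParameterError("t must be strictly increasing")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(p))):
        raise InvalidParameterError("non-finite values in input")

    n = len(t)
    if np.ptp(p) < 1e-10:
        return TrajectoryFit(
            S=math.nan, lam=math.nan, L=float(p[0]), U=float(p[0]),
            rss=0.0, converged=False, n_points=n,
            message="flat trajectory: steepness unidentifiable",
        )

    params, rss, ok, message = _fit_core(t, p, fix_asymptotes)
    fit = TrajectoryFit(
        S=float(params[0]), lam=float(params[1]), L=float(params[2]),
        U=float(params[3]), rss=rss, converged=ok, n_points=n, message=message,
    )
    if ci and ok:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            idx = np.sort(rng.integers(0, n, size=n))
            bt, bp = t[idx], p[idx]
            if np.ptp(bp) < 1e-10 or len(np.unique(bt)) < 3:
                continue
            try:
                bpar, _, bok, _ = _fit_core(bt, bp, fix_asymptotes)
            except Exception:  # pragma: no cover - pathological resample
                continue
            if bok:
                boots.append(bpar)
        if len(boots) >= 20:
            arr = np.array(boots)
            lohi = np.percentile(arr, [2.5, 97.5], axis=0)
            fit.ci = {
                name: (float(lohi[0, i]), float(lohi[1, i]))
                for i, name in enumerate(["S", "lam", "L", "U"])
            }
    return fit


def adaptation_summary(fit_table: pd.DataFrame) -> tuple[pd.DataFrame, CorrelationTest]:
    """Per-bottleneck summary of adaptation fits across parallel populations.

    ``fit_table`` needs columns ``population_id``, ``D``, ``S``, ``lam``,
    ``L``, ``U`` and ``final_log10_pf`` (final-cycle log10 persister
    fraction). Returns one row per bottleneck group (mean S, mean lag,
    log10 fold-increase U - L, across-population variance of the final
    log10 persister fraction) plus the Spearman test of S against D over
    all populations. Empty groups are omitted with a warning.
    """
    required = {"population_id", "D", "S", "lam", "L", "U", "final_log10_pf"}
    missing = required - set(fit_table.columns)
    if missing:
        raise InvalidParameterError(f"fit_table missing columns: {sorted(missing)}")
    clean = fit_table.dropna(subset=["S", "lam"])
    dropped = len(fit_table) - len(clean)
    if dropped:
        warnings.warn(f"omitted {dropped} non-converged fits", UserWarning)
    groups = clean.groupby("D")
    if groups.ngroups < 2:
        raise InvalidParameterError("need >= 2 bottleneck groups")
    rows = []
    for d, g in groups:
        rows.append(
            {
                "D": d,
                "n_populations": len(g),
                "mean_S": g["S"].mean(),
                "mean_lam": g["lam"].mean(),
                "mean_log10_fold_increase": (g["U"] - g["L"]).mean(),
                "var_final_log10_pf": g["final_log10_pf"].var(ddof=1) if len(g) > 1 else math.nan,
            }
        )
    summary = pd.DataFrame(rows).sort_values("D").reset_index(drop=True)
    try:
        corr = spearman_exact(clean["D"].to_numpy(), clean["S"].to_numpy())
    except ConstantInputError:
        warnings.warn("steepness constant across populations: trend test undefined", UserWarning)
        corr = None
    return summary, corr
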