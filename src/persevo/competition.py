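"""Fitness estimators and the dilution-corrected mutant-spread recurrence.

Three independent fitness readouts are implemented:

* a competition coefficient from growth-curve areas,
  ``AUC_mixed = c * AUC_mono + (1 - c) * AUC_anc`` (c = 0.5 means no
  competitive advantage over the ancestor);
* a per-round relative fitness ``W_A`` from head-to-head frequency counts
  (odds ratio across one selection round);
* a deterministic recurrence for the spread of a mutant under serial
  dilution, ``p(T+1) = W_eff p / (W_eff p + q)``, where bottlenecking at
  dilution ratio D rescales the selection coefficient by the factor
  ``D (ln D)^2``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    BoundaryFitnessWarning,
    InvalidParameterError,
    UndefinedCoefficientError,
)

__all__ = [
    "CompetitionResult",
    "SpreadTrajectory",
    "auc_trapezoid",
    "competition_coefficient",
    "relative_fitness",
    "spread_correction",
    "effective_fitness",
    "mutant_spread",
    "mutant_spread_closed_form",
]


@dataclass(frozen=True)
class CompetitionResult:
    c: float | None = None
    W_A: float | None = None


@dataclass(frozen=True)
class SpreadTrajectory:
    """Deterministic mutant-frequency trajectory over selection rounds."""

    D: float
    W_A: float
    correction: float
    p: np.ndarray  # p[T], T = 0..T_max
    q: np.ndarray  # 1 - p[T]


def auc_trapezoid(t, od) -> float:
    """Trapezoidal area under an optical-density record (OD * time units)."""
    t = np.asarray(t, dtype=float)
    od = np.asarray(od, dtype=float)
    if t.shape != od.shape or t.ndim != 1 or len(t) < 2:
        raise InvalidParameterError("need >= 2 paired (t, od) points")
    if np.any(np.diff(t) <= 0):
        raise InvalidParameterError("t must be strictly increasing")
    if np.any(od < 0):
        raise InvalidParameterError("optical densities must be >= 0")
    return float(np.trapezoid(od, t))


def competition_coefficient(auc_mixed: float, auc_mono: float, auc_anc: float) -> float:
    """c = (AUC_mixed - AUC_anc) / (AUC_mono - AUC_anc)."""
    if auc_mono == auc_anc:
        raise UndefinedCoefficientError(
            "competition coefficient undefined: AUC_mono == AUC_anc"
        )
    return (auc_mixed - auc_anc) / (auc_mono - auc_anc)


def relative_fitness(freq_before: float, freq_after: float) -> float:
    """Relative fitness W_A = odds(freq_after) / odds(freq_before).

    One "round" spans the full assay (growth, treatment, growth). W_A = 1
    means no frequency change. Boundary ``freq_after`` in {0, 1} returns 0
    or inf with a warning rather than raising.
    """
    if not 0.0 < freq_before < 1.0:
        raise InvalidParameterError("freq_before must be strictly inside (0, 1)")
    if not 0.0 <= freq_after <= 1.0:
        raise InvalidParameterError("freq_after must be in [0, 1]")
    odds_before = freq_before / (1.0 - freq_before)
    if freq_after == 1.0:
        warnings.warn("mutant fixed: infinite relative fitness", BoundaryFitnessWarning)
        return math.inf
    if freq_after == 0.0:
        warnings.warn("mutant lost: zero relative fitness", BoundaryFitnessWarning)
        return 0.0
    return (freq_after / (1.0 - freq_after)) / odds_before


def spread_correction(D: float) -> float:
    """Serial-dilution correction factor D (ln D)^2 for the spread rate."""
    if not 0.0 < D < 1.0:
        raise InvalidParameterError(
            f"D must be in (0, 1): the correction degenerates to 0 at D = 1 (got {D})"
        )
    return D * math.log(D) ** 2


def effective_fitness(W_A: float, D: float, mode: str = "selection_coeff") -> float:
    """Per-round fitness after the bottleneck correction.

    ``selection_coeff`` (default) rescales the selection coefficient,
    ``W_eff = 1 + (W_A - 1) * D (ln D)^2``, leaving neutral mutants
    invariant; ``log_fitness`` rescales log-fitness,
    ``W_eff = W_A ** (D (ln D)^2)``.
    """
    if W_A <= 0:
        raise InvalidParameterError("W_A must be > 0")
    corr = spread_correction(D)
    if mode == "selection_coeff":
        return 1.0 + (W_A - 1.0) * corr
    if mode == "log_fitness":
        return W_A**corr
    raise InvalidParameterError(f"unknown correction mode {mode!r}")


def mutant_spread(
    W_A: float,
    D: float,
    p0: float = 1e-8,
    T_max: int = 100,
    mode: str = "selection_coeff",
) -> SpreadTrajectory:
    """Iterate the corrected selection recurrence for ``T_max`` rounds.

    p(T+1) = W_eff p(T) / (W_eff p(T) + q(T)), with q renormalized so
    p + q = 1 holds exactly at every step. The default start frequency is
    one mutant cell in 10^8.
    """
    if not 0.0 < p0 < 1.0:
        raise InvalidParameterError("p0 must be strictly inside (0, 1)")
    if T_max < 0:
        raise InvalidParameterError("T_max must be >= 0")
    W_eff = effective_fitness(W_A, D, mode=mode)
    p = np.empty(T_max + 1)
    p[0] = p0
    for T in range(T_max):
        num = W_eff * p[T]
        p[T + 1] = num / (num + (1.0 - p[T]))
    return SpreadTrajectory(
        D=D, W_A=W_A, correction=spread_correction(D), p=p, q=1.0 - p
    )


def mutant_spread_closed_form(
    W_A: float,
    D: float,
    p0: float = 1e-8,
    T: int = 100,
    mode: str = "selection_coeff",
) -> float:
    """Closed form p(T) = W_eff^T p0 / (W_eff^T p0 + 1 - p0)."""
    if not 0.0 < p0 < 1.0:
        raise InvalidParameterError("p0 must be strictly inside (0, 1)")
    W_eff = effective_fitness(W_A, D, mode=mode)
    # work in logs to survive large T
    log_num = T * math.log(W_eff) + math.log(p0)
    num = math.exp(log_num)
    return num / (num + (1.0 - p0))
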