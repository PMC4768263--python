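"""Median-effect dose-response fitting and the Chou-Talalay combination index.

The median-effect model relates dose D to fraction affected fa through

    fa / (1 - fa) = (D / Dm)^m

so log10(fa/(1-fa)) is linear in log10(D): slope m (sigmoidicity) and
x-intercept log10(Dm) (the dose for half effect).  For two drugs combined
at doses (d1, d2) producing a joint effect fa, the combination index is

    CI = d1/Dx1(fa) + d2/Dx2(fa)

where Dxi(fa) is the dose of drug i alone required for effect fa.
CI < 1 indicates synergy, CI = 1 additivity, CI > 1 antagonism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .stats import pearson

__all__ = ["DoseResponsePoint", "MedianEffectFit", "CombinationIndexResult",
           "fit_median_effect", "fa_at", "required_dose", "combination_index"]

#: CI within this band of 1 is called additive
ADDITIVITY_TOL = 1e-9
#: fa closer than this to 0 or 1 is rejected (logit blows up)
FA_GUARD = 1e-12


@dataclass(frozen=True)
class DoseResponsePoint:
    """One (dose, fraction affected) reading; fa = 1 - relative survival."""

    dose: float
    fraction_affected: float

    def __post_init__(self) -> None:
        if not self.dose > 0:
            raise ValueError(f"dose must be positive, got {self.dose}")
        fa = self.fraction_affected
        if not FA_GUARD <= fa <= 1.0 - FA_GUARD:
            raise ValueError(
                f"fraction_affected must lie strictly inside (0, 1), got {fa}"
            )


@dataclass(frozen=True)
class MedianEffectFit:
    """Fitted median-effect parameters.

    m       slope of the median-effect plot
    Dm      dose producing fa = 0.5
    fit_r   Pearson r of the log-linear fit (quality diagnostic)
    """

    m: float
    Dm: float
    fit_r: float
    n_points: int


@dataclass(frozen=True)
class CombinationIndexResult:
    ci: float
    fa: float
    d1: float
    d2: float
    classification: str  # "synergy" | "additivity" | "antagonism"


def fit_median_effect(points: Sequence[DoseResponsePoint]) -> MedianEffectFit:
    """Ordinary least squares on the median-effect plot.

    Regresses log10(fa/(1-fa)) on log10(dose); requires at least two
    distinct doses.  A flat fit (m = 0) leaves Dm undefined and is an error.
    """
    points = list(points)
    if len(points) < 2:
        raise ValueError("median-effect fit needs at least 2 points")
    doses = np.array([p.dose for p in points])
    fa = np.array([p.fraction_affected for p in points])
    if np.unique(doses).size < 2:
        raise ValueError("median-effect fit needs at least 2 distinct doses")
    x = np.log10(doses)
    y = np.log10(fa / (1.0 - fa))
    m, intercept = np.polyfit(x, y, 1)
    if m == 0:
        raise ValueError("flat median-effect fit (m = 0): Dm is undefined")
    if len(points) >= 3 and np.ptp(y) > 0:
        fit_r = pearson(x, y).r
    else:
        fit_r = 1.0 if m > 0 else -1.0
    return MedianEffectFit(m=float(m), Dm=float(10.0 ** (-intercept / m)),
                           fit_r=float(fit_r), n_points=len(points))


def fa_at(fit: MedianEffectFit, dose: float) -> float:
    """Forward median-effect map: fraction affected at ``dose``."""
    if not dose > 0:
        raise ValueError("dose must be positive")
    odds = (dose / fit.Dm) ** fit.m
    return odds / (1.0 + odds)


def required_dose(fit: MedianEffectFit, fa: float) -> float:
    """Dose of the drug alone needed for effect ``fa``:
    Dx = Dm * (fa/(1-fa))^(1/m)."""
    if not FA_GUARD <= fa <= 1.0 - FA_GUARD:
        raise ValueError(
            f"fa must lie strictly inside (0, 1), got {fa}"
        )
    return fit.Dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)


def combination_index(fit1: MedianEffectFit, fit2: MedianEffectFit,
                      d1: float, d2: float,
                      fa_combo: float) -> CombinationIndexResult:
    """Non-constant-ratio Chou-Talalay CI at the observed combination effect.

    Each drug contributes the ratio of its combination dose to the dose it
    would need alone to reach ``fa_combo``.
    """
    if d1 < 0 or d2 < 0 or (d1 == 0 and d2 == 0):
        raise ValueError("doses must be >= 0 and not both zero")
    dx1 = required_dose(fit1, fa_combo)
    dx2 = required_dose(fit2, fa_combo)
    ci = d1 / dx1 + d2 / dx2
    if abs(ci - 1.0) <= ADDITIVITY_TOL:
        classification = "additivity"
    elif ci < 1.0:
        classification = "synergy"
    else:
        classification = "antagonism"
    return CombinationIndexResult(ci=float(ci), fa=fa_combo, d1=d1, d2=d2,
                                  classification=classification)
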