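"""Scalar pharmacology calculators.

Small, pure functions for the study endpoints: percent maximum possible
effect (%MPE), ED50 from a normalized dose-response, PET standardized
uptake value (SUV), unbound concentrations from plasma-protein binding,
brain/plasma ratios, microsomal percent remaining, fold differences, and
the naloxone-precipitated withdrawal score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "WithdrawalObservation",
    "CHECKED_SIGN_POINTS",
    "percent_mpe",
    "suv",
    "unbound",
    "brain_plasma_ratio",
    "percent_remaining",
    "fold_difference",
    "withdrawal_score",
    "withdrawal_score_multi",
    "ed50",
]

#: point value of each present/absent withdrawal sign
CHECKED_SIGN_POINTS = {
    "abdominal_spasms": 2,
    "abnormal_posture": 3,
    "diarrhea": 2,
    "irritability_vocalization": 3,
    "genital_grooming": 3,
    "profuse_salivation": 7,
    "ptosis": 2,
    "swallowing_movements": 2,
    "teeth_chattering": 2,
}


def percent_mpe(measure: float, baseline: float, max_response: float) -> float:
    """%MPE = (measure - baseline) / (max_response - baseline) * 100.

    May exceed 100 only if the measure exceeds the stated maximum (cutoffs
    normally cap measures); such values are flagged with a warning.
    """
    if max_response <= baseline:
        raise ValueError("max_response must exceed baseline")
    mpe = 100.0 * (measure - baseline) / (max_response - baseline)
    if measure > max_response:
        warnings.warn("measure exceeds the stated maximum response; %MPE > 100")
    return mpe


def suv(tissue_conc_kbq_ml: float, dose_mbq: float, body_weight_kg: float) -> float:
    """Standardized uptake value, SUV = C / (dose / BW).

    With C in kBq/ml, dose in MBq and body weight in kg, the quotient is
    dimensionless up to the conventional 1 g/ml tissue-density factor.
    """
    if dose_mbq <= 0:
        raise ValueError("dose must be positive")
    if body_weight_kg <= 0:
        raise ValueError("body weight must be positive")
    return tissue_conc_kbq_ml / (dose_mbq / body_weight_kg)


def unbound(total_conc: float, ppb: float) -> float:
    """Unbound concentration given the plasma-protein-bound fraction."""
    if not 0.0 <= ppb < 1.0:
        raise ValueError("plasma protein binding must be in [0, 1)")
    return total_conc * (1.0 - ppb)


def brain_plasma_ratio(brain_unbound: float, plasma_unbound: float) -> float:
    """Unbound brain/plasma quotient; >1 suggests accumulation, <1 efflux."""
    if plasma_unbound <= 0:
        raise ValueError("plasma concentration must be positive")
    return brain_unbound / plasma_unbound


def percent_remaining(conc_t: float, conc_0: float) -> float:
    """Metabolic stability: 100 * C(t) / C(0)."""
    if conc_0 <= 0:
        raise ValueError("baseline concentration must be positive")
    return 100.0 * conc_t / conc_0


def fold_difference(a: float, b: float) -> float:
    """Simple a/b fold difference (e.g. of ED50s or peak doses)."""
    if b <= 0:
        raise ValueError("denominator must be positive")
    return a / b


@dataclass
class WithdrawalObservation:
    """One rater's somatic withdrawal observations for one animal."""

    jump_attempts: int = 0
    paw_tremors: int = 0
    wet_dog_shakes: int = 0
    fecal_deposits: int = 0
    checked_signs: set[str] = field(default_factory=set)
    weight_loss_g: float = 0.0
    rater_id: str = ""

    def __post_init__(self) -> None:
        for name in ("jump_attempts", "paw_tremors", "wet_dog_shakes", "fecal_deposits"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        unknown = self.checked_signs - set(CHECKED_SIGN_POINTS)
        if unknown:
            raise ValueError(f"unknown checked signs: {sorted(unknown)}")
        if self.weight_loss_g < 0:
            raise ValueError("weight loss must be >= 0")


def _graded(count: int, brackets: list[tuple[int, int, int]]) -> int:
    for lo, hi, points in brackets:
        if lo <= count <= hi:
            return points
    return 0


def withdrawal_score(obs: WithdrawalObservation) -> float:
    """Weighted somatic withdrawal score for a single rater.

    Graded signs: jump attempts 1 point (1-4), 2 (5-10), 3 (>10); paw
    tremors 2 (1-2), 4 (>=3); wet dog shakes 1 (1-2), 2 (>=3); fecal
    deposits 1 point each.  Checked signs carry fixed points (salivation 7,
    posture/irritability/grooming 3, others 2).  Weight loss contributes
    1 point per gram, rounded to the nearest gram.
    """
    score = 0.0
    score += _graded(obs.jump_attempts, [(1, 4, 1), (5, 10, 2), (11, 10**9, 3)])
    score += _graded(obs.paw_tremors, [(1, 2, 2), (3, 10**9, 4)])
    score += _graded(obs.wet_dog_shakes, [(1, 2, 1), (3, 10**9, 2)])
    score += obs.fecal_deposits
    score += sum(CHECKED_SIGN_POINTS[s] for s in obs.checked_signs)
    score += round(obs.weight_loss_g)
    return score


def withdrawal_score_multi(observations: list[WithdrawalObservation]) -> float:
    """Overall score: per-rater totals averaged across raters.

    By linearity this equals summing per-sign scores after averaging each
    sign across raters.
    """
    if not observations:
        raise ValueError("at least one observation required")
    return float(np.mean([withdrawal_score(o) for o in observations]))


def ed50(dose: np.ndarray, mpe_pct: np.ndarray, bottom: float = 0.0,
         top: float = 100.0) -> float:
    """ED50 from mean %MPE vs dose by normalized logistic regression.

    Asymptotes are fixed (0 and 100 on the %MPE scale); only the ED50 is
    free.  Dose units are preserved.  Flat, non-monotone data are flagged
    with a ValueError rather than fitted.
    """
    d = np.asarray(dose, dtype=float)
    y = np.asarray(mpe_pct, dtype=float)
    if len(np.unique(d)) < 3:
        raise ValueError("at least 3 doses are required")
    if np.any(d <= 0):
        raise ValueError("doses must be positive")
    if np.ptp(y) < 1e-9:
        raise ValueError("flat dose-response: ED50 not identifiable")
    logd = np.log10(d)
    span = top - bottom

    def model(lx, led50):
        return bottom + span / (1.0 + 10.0 ** (led50 - lx))

    half = bottom + span / 2.0
    led0 = float(logd[np.argmin(np.abs(y - half))])
    popt, _ = curve_fit(model, logd, y, p0=[led0], maxfev=10000)
    return float(10.0 ** popt[0])
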