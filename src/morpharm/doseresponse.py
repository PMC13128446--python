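"""Concentration-response, competition and kinetic binding curve fitting.

The workhorse model is the three-parameter logistic (Hill slope fixed at 1)

    y(x) = bottom + (top - bottom) / (1 + EC50 / x)

fitted on log10 concentration with pEC50 = -log10(EC50) as the free
parameter for numerical conditioning.  Radioligand kinetics use the
standard one-site association/dissociation models

    dissociation:  B(t) = B0 * exp(-k_off * t)
    association:   B(t) = Beq * (1 - exp(-k_obs * t)),  k_obs = k_on*L + k_off

and competition IC50s convert to Ki via Cheng-Prusoff,
Ki = IC50 / (1 + L/Kd).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "LogisticFit",
    "KineticFit",
    "AffinityEstimate",
    "fit_logistic3",
    "fit_table",
    "normalize_to_damgo",
    "subtract_ligand_free",
    "cheng_prusoff",
    "fit_dissociation",
    "fit_association",
    "one_site_competition",
]

LN2 = np.log(2.0)


@dataclass
class LogisticFit:
    """Result of a three-parameter logistic fit.

    ``emax`` on a DAMGO-normalized input scale equals ``top``; ``span``
    (top - bottom) is the maximal net response used for %Emax bookkeeping.
    """

    bottom: float
    top: float
    ec50: float
    pec50: float
    cov: np.ndarray | None = None
    converged: bool = True
    message: str = ""
    direction: str = "increasing"

    @property
    def span(self) -> float:
        return self.top - self.bottom

    def predict(self, conc: np.ndarray) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        return self.bottom + self.span / (1.0 + self.ec50 / conc)


@dataclass
class KineticFit:
    """One-site binding kinetics.  t_half = ln2/k_off holds by construction."""

    k_off: float
    t_half: float = field(init=False)
    k_obs: float = np.nan
    k_on: float = np.nan
    b0: float = np.nan
    beq: float = np.nan
    ligand_conc: float = np.nan
    converged: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        self.t_half = LN2 / self.k_off if self.k_off > 0 else np.nan


@dataclass
class AffinityEstimate:
    ic50: float
    ki: float
    ligand_conc: float
    kd: float
    fit: LogisticFit | None = None


def _logistic(logx: np.ndarray, bottom: float, span: float, pec50: float) -> np.ndarray:
    # y = bottom + span / (1 + 10**(-(logx + pec50))); midpoint at x = EC50
    return bottom + span / (1.0 + 10.0 ** (-(logx + pec50)))


def _initial_guess(logx: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    # dose-averaged responses give robust asymptote starts; pEC50 from the
    # concentration whose mean response is closest to the half-span
    order = np.argsort(logx)
    ux, inv = np.unique(logx[order], return_inverse=True)
    means = np.array([y[order][inv == i].mean() for i in range(len(ux))])
    bottom0, top0 = float(means.min()), float(means.max())
    half = 0.5 * (bottom0 + top0)
    pec0 = float(-ux[np.argmin(np.abs(means - half))])
    return bottom0, top0 - bottom0, pec0


def fit_logistic3(
    concentration: np.ndarray,
    response: np.ndarray,
    direction: str = "increasing",
) -> LogisticFit:
    """Least-squares three-parameter logistic fit.

    Parameters
    ----------
    concentration : array of molar concentrations, strictly positive.
    response : matching responses; replicates are pooled (equal weights).
    direction : "increasing" for agonist curves, "decreasing" for
        competition binding (response falls with concentration).

    Raises ``ValueError`` for fewer than 4 distinct concentrations or
    non-positive concentrations.  Non-convergent or degenerate fits are
    returned with ``converged=False`` rather than silently.
    """
    conc = np.asarray(concentration, dtype=float)
    y = np.asarray(response, dtype=float)
    if conc.shape != y.shape:
        raise ValueError("concentration and response must have equal length")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    if len(np.unique(conc)) < 4:
        raise ValueError("at least 4 distinct concentrations are required")

    logx = np.log10(conc)
    if direction == "decreasing":
        # fit the mirrored curve and swap asymptotes back afterwards
        inner = fit_logistic3(conc, -y, direction="increasing")
        return LogisticFit(
            bottom=-inner.top,
            top=-inner.bottom,
            ec50=inner.ec50,
            pec50=inner.pec50,
            cov=inner.cov,
            converged=inner.converged,
            message=inner.message,
            direction="decreasing",
        )
    if direction != "increasing":
        raise ValueError(f"unknown direction: {direction!r}")

    bottom0, span0, pec0 = _initial_guess(logx, y)
    if span0 <= 0 or np.ptp(y) == 0:
        return LogisticFit(
            bottom=float(y.mean()), top=float(y.mean()), ec50=np.nan,
            pec50=np.nan, converged=False,
            message="constant responses: EC50 not identifiable",
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                _logistic, logx, y,
                p0=[bottom0, span0, pec0],
                bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
    except RuntimeError as exc:  # pragma: no cover - scipy failure path
        return LogisticFit(bottom0, bottom0 + span0, 10.0 ** -pec0, pec0,
                           converged=False, message=str(exc))
    bottom, span, pec50 = popt
    ok = bool(np.all(np.isfinite(pcov)))
    return LogisticFit(
        bottom=float(bottom), top=float(bottom + span), ec50=float(10.0 ** -pec50),
        pec50=float(pec50), cov=pcov, converged=ok,
        message="" if ok else "covariance not estimable (flat or unbracketed curve)",
    )


def fit_table(
    df: pd.DataFrame,
    conc_col: str = "conc_M",
    response_col: str = "response",
    by: tuple[str, ...] = ("compound",),
) -> pd.DataFrame:
    """Fit every group of a long-format plate table and tabulate the results.

    Rows with non-positive concentration (ligand-free wells) are excluded
    from the fit.  Output columns: group keys, pEC50, EC50_nM, bottom, top,
    Emax (top), converged.
    """
    rows = []
    for keys, g in df[df[conc_col] > 0].groupby(list(by), sort=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        fit = fit_logistic3(g[conc_col].to_numpy(), g[response_col].to_numpy())
        rows.append(dict(zip(by, keys)) | {
            "pEC50": fit.pec50,
            "EC50_nM": fit.ec50 * 1e9,
            "bottom": fit.bottom,
            "top": fit.top,
            "converged": fit.converged,
        })
    return pd.DataFrame(rows)


def subtract_ligand_free(df: pd.DataFrame, response_col: str = "response",
                         conc_col: str = "conc_M") -> pd.DataFrame:
    """Subtract the mean ligand-free (zero-concentration) well reading.

    Background correction applied before raw-scale fitting; ligand-free
    rows are dropped from the returned table.
    """
    blank = df.loc[df[conc_col] <= 0, response_col]
    if blank.empty:
        return df.copy()
    out = df[df[conc_col] > 0].copy()
    out[response_col] = out[response_col] - blank.mean()
    return out


def normalize_to_damgo(values: np.ndarray | float, damgo_fit: LogisticFit) -> np.ndarray | float:
    """Express responses as % of the DAMGO reference span.

    y' = 100 * (y - damgo.bottom) / (damgo.top - damgo.bottom).  Values
    above the DAMGO top map above 100% (supramaximal efficacy).
    """
    span = damgo_fit.span
    if span <= 0:
        raise ValueError("DAMGO span must be positive to normalize")
    return 100.0 * (np.asarray(values, dtype=float) - damgo_fit.bottom) / span


def cheng_prusoff(ic50: float, ligand_conc: float, kd: float) -> float:
    """Ki from a competition IC50: Ki = IC50 / (1 + L/Kd)."""
    if ic50 <= 0:
        raise ValueError("IC50 must be positive")
    if kd <= 0:
        raise ValueError("radioligand Kd must be positive")
    if ligand_conc < 0:
        raise ValueError("radioligand concentration must be >= 0")
    return ic50 / (1.0 + ligand_conc / kd)


def fit_dissociation(time_min: np.ndarray, bound: np.ndarray) -> KineticFit:
    """Fit B(t) = B0 * exp(-k_off t) to a specific-binding decay series.

    Requires >= 5 timepoints spanning at least one half-life of decay.
    A non-decaying series is returned flagged, not silently fitted.
    """
    t = np.asarray(time_min, dtype=float)
    b = np.asarray(bound, dtype=float)
    if len(t) < 5:
        raise ValueError("at least 5 timepoints are required")
    slope = np.polyfit(t, b, 1)[0]
    if slope >= 0:
        fit = KineticFit(k_off=np.nan)
        fit.converged = False
        fit.message = "series does not decay; k_off not estimable"
        return fit
    b0_guess = float(b[np.argmin(t)])
    koff_guess = max(-slope / max(b0_guess, 1e-12), 1e-6)
    popt, _ = curve_fit(
        lambda tt, b0, k: b0 * np.exp(-k * tt), t, b,
        p0=[b0_guess, koff_guess], bounds=([0, 1e-12], [np.inf, np.inf]),
        maxfev=20000,
    )
    fit = KineticFit(k_off=float(popt[1]))
    fit.b0 = float(popt[0])
    return fit


def fit_association(
    time_min: np.ndarray,
    bound: np.ndarray,
    k_off: float,
    ligand_conc: float,
) -> KineticFit:
    """Fit B(t) = Beq*(1 - exp(-k_obs t)) with k_off fixed from dissociation.

    k_on = (k_obs - k_off) / L.  A fitted k_obs below the supplied k_off
    yields a negative, non-physical k_on and is flagged.
    """
    if k_off <= 0:
        raise ValueError("k_off must be positive")
    if ligand_conc <= 0:
        raise ValueError("ligand concentration must be positive")
    t = np.asarray(time_min, dtype=float)
    b = np.asarray(bound, dtype=float)
    beq_guess = float(np.max(b)) or 1.0
    popt, _ = curve_fit(
        lambda tt, beq, kobs: beq * (1.0 - np.exp(-kobs * tt)), t, b,
        p0=[beq_guess, max(2.0 * k_off, 1e-3)],
        bounds=([0, 1e-12], [np.inf, np.inf]), maxfev=20000,
    )
    beq, kobs = popt
    fit = KineticFit(k_off=float(k_off))
    fit.k_obs = float(kobs)
    fit.beq = float(beq)
    fit.ligand_conc = float(ligand_conc)
    fit.k_on = float((kobs - k_off) / ligand_conc)
    if kobs < k_off:
        fit.converged = False
        fit.message = "fitted k_obs < k_off: k_on non-physical"
    return fit


def one_site_competition(
    concentration: np.ndarray,
    response: np.ndarray,
    ligand_conc: float,
    kd: float,
) -> AffinityEstimate:
    """One-site competition fit: IC50 from the logistic inflection, Ki via
    Cheng-Prusoff given the radioligand concentration and Kd."""
    fit = fit_logistic3(concentration, response, direction="decreasing")
    if fit.converged:
        conc = np.asarray(concentration, dtype=float)
        y = np.asarray(response, dtype=float)
        lo, hi = np.argmin(conc), np.argmax(conc)
        if y[hi] > y[lo]:
            fit.converged = False
            fit.message = "response increases with concentration: wrong orientation"
    ic50 = fit.ec50
    ki = cheng_prusoff(ic50, ligand_conc, kd) if np.isfinite(ic50) else np.nan
    return AffinityEstimate(ic50=ic50, ki=ki, ligand_conc=ligand_conc, kd=kd, fit=fit)
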