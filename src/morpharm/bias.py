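"""Functional-kinetics bias analysis of BRET time courses.

Each timepoint of a kinetic BRET experiment is fitted with a
three-parameter logistic on the raw BRET ratio.  The net BRET response is
the raw response minus the *fitted* curve minimum, the maximal net BRET
(the fitted span) is normalized to the reference (DAMGO) span at the same
timepoint to give %Emax, and pathway engagement is summarized by a proxy
transduction index

    TI = log10(%Emax / EC50)

Bias at timepoint x is the DAMGO-referenced double difference

    dTI = TI_compound - TI_DAMGO        (per pathway)
    bias_x = dTI(Go) - dTI(beta-arrestin 2)

with errors propagated in quadrature:

    sem      = sd / sqrt(n)                      (across experiments)
    SE_assay = sqrt(sem_compound^2 + sem_DAMGO^2)
    SE_final = sqrt(SE_Go^2 + SE_barr2^2)

TI is a proxy, deliberately distinct from the operational-model
transduction coefficient log(tau/KA); bias differences cancel the EC50
unit convention, so only the reporting scale is affected by it.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .doseresponse import LogisticFit, fit_logistic3

__all__ = [
    "net_bret",
    "transduction_index",
    "bias_factor",
    "propagate_se",
    "efficacy_decline",
    "timecourse_pharmacology",
    "bias_table",
]

PATHWAYS = ("Go", "barr2")


def net_bret(raw_values: np.ndarray | float, raw_fit: LogisticFit) -> np.ndarray | float:
    """Raw BRET responses minus the fitted curve minimum (not the data min)."""
    if not raw_fit.converged:
        raise ValueError(f"raw-scale fit did not converge: {raw_fit.message}")
    return np.asarray(raw_values, dtype=float) - raw_fit.bottom


def transduction_index(emax_pct: float, ec50: float, base: float = 10.0) -> float:
    """TI = log(%Emax / EC50); EC50 in molar by convention, log base 10."""
    if emax_pct <= 0 or ec50 <= 0:
        raise ValueError("emax_pct and ec50 must be positive")
    return math.log(emax_pct / ec50, base)


def bias_factor(
    ti_compound_go: float,
    ti_damgo_go: float,
    ti_compound_barr: float,
    ti_damgo_barr: float,
) -> tuple[float, float, float]:
    """(dTI_Go, dTI_barr2, bias) for one compound at one timepoint."""
    d_go = ti_compound_go - ti_damgo_go
    d_barr = ti_compound_barr - ti_damgo_barr
    return d_go, d_barr, d_go - d_barr


def propagate_se(
    sd_compound_go: float, n_compound_go: int,
    sd_damgo_go: float, n_damgo_go: int,
    sd_compound_barr: float, n_compound_barr: int,
    sd_damgo_barr: float, n_damgo_barr: int,
) -> dict[str, float]:
    """Root-sum-square error propagation through dTI and bias.

    Returns sem per compound/pathway, SE_assay per pathway and SE_final.
    """
    vals = {}
    for name, sd, n in [
        ("sem_compound_Go", sd_compound_go, n_compound_go),
        ("sem_damgo_Go", sd_damgo_go, n_damgo_go),
        ("sem_compound_barr2", sd_compound_barr, n_compound_barr),
        ("sem_damgo_barr2", sd_damgo_barr, n_damgo_barr),
    ]:
        if n < 1:
            raise ValueError("number of experiments must be >= 1")
        if sd < 0:
            raise ValueError("standard deviations must be >= 0")
        vals[name] = sd / math.sqrt(n)
    vals["SE_assay_Go"] = math.hypot(vals["sem_compound_Go"], vals["sem_damgo_Go"])
    vals["SE_assay_barr2"] = math.hypot(vals["sem_compound_barr2"], vals["sem_damgo_barr2"])
    vals["SE_final"] = math.hypot(vals["SE_assay_Go"], vals["SE_assay_barr2"])
    return vals


def efficacy_decline(e_initial_pct: float, e_plateau_pct: float) -> float:
    """Drop in %Emax from the first grid point to the plateau, in points."""
    return e_initial_pct - e_plateau_pct


def _fit_timepoint(g: pd.DataFrame) -> LogisticFit:
    return fit_logistic3(g["conc_M"].to_numpy(), g["response"].to_numpy())


def timecourse_pharmacology(
    plate: pd.DataFrame,
    reference: str = "DAMGO",
) -> pd.DataFrame:
    """Per-timepoint %Emax and pEC50 for every compound in a kinetic plate.

    ``plate`` is long format with columns compound, conc_M, timepoint_min,
    replicate, response (raw BRET ratio), and optionally pathway.  For each
    pathway x timepoint, raw curves are fitted per compound, net BRET is
    taken against each fitted minimum, and the compound's maximal net BRET
    (fitted span) is normalized to the reference span at the same
    timepoint: %Emax = 100 * span_compound / span_reference.

    Timepoints whose reference curve is missing or unconverged are skipped
    with a warning and reported as gaps, never interpolated.
    """
    required = {"compound", "conc_M", "timepoint_min", "response"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate is missing columns: {sorted(missing)}")
    has_pathway = "pathway" in plate.columns
    groups = ["pathway", "timepoint_min"] if has_pathway else ["timepoint_min"]
    rows = []
    for keys, sub in plate.groupby(groups, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        info = dict(zip(groups, keys))
        if reference not in set(sub["compound"]):
            warnings.warn(f"timepoint {info} skipped: reference {reference!r} absent")
            continue
        ref_fit = _fit_timepoint(sub[sub["compound"] == reference])
        if not ref_fit.converged or ref_fit.span <= 0:
            warnings.warn(f"timepoint {info} skipped: reference fit unusable")
            continue
        for compound, g in sub.groupby("compound", sort=False):
            fit = _fit_timepoint(g)
            n_exp = g["replicate"].nunique() if "replicate" in g.columns else 1
            rows.append(info | {
                "compound": compound,
                "emax_pct": 100.0 * fit.span / ref_fit.span,
                "pec50": fit.pec50,
                "ec50_M": fit.ec50,
                "n_experiments": int(n_exp),
                "converged": fit.converged,
            })
    return pd.DataFrame(rows)


def _per_experiment_ti(sub: pd.DataFrame, reference: str) -> pd.DataFrame:
    """TI per compound per independent experiment at one pathway/timepoint."""
    rows = []
    for rep, g in sub.groupby("replicate", sort=True):
        if reference not in set(g["compound"]):
            continue
        ref_fit = _fit_timepoint(g[g["compound"] == reference])
        if not ref_fit.converged or ref_fit.span <= 0:
            continue
        for compound, gc in g.groupby("compound", sort=False):
            fit = _fit_timepoint(gc)
            if not fit.converged or fit.span <= 0:
                continue
            emax_pct = 100.0 * fit.span / ref_fit.span
            rows.append({
                "replicate": rep,
                "compound": compound,
                "ti": transduction_index(emax_pct, fit.ec50),
            })
    return pd.DataFrame(rows)


def bias_table(plate: pd.DataFrame, reference: str = "DAMGO") -> pd.DataFrame:
    """Full bias calculus over a two-pathway kinetic plate.

    TI is computed per independent experiment (replicate) and averaged;
    the across-experiment s.d. enters the s.e.m.  Output: one row per
    compound x timepoint with TI, dTI, bias and propagated SEs.  The
    reference compound's dTI and bias are identically 0.
    """
    for col in ("pathway", "replicate"):
        if col not in plate.columns:
            raise ValueError(f"bias_table requires a {col!r} column")
    pathways = sorted(set(plate["pathway"]))
    unknown = set(pathways) - set(PATHWAYS)
    if unknown:
        raise ValueError(f"unknown pathways {sorted(unknown)}; expected {PATHWAYS}")

    # mean/sd/n of per-experiment TI per (pathway, timepoint, compound)
    stats: dict[tuple, dict[str, dict]] = {}
    for (pathway, tp), sub in plate.groupby(["pathway", "timepoint_min"], sort=True):
        tis = _per_experiment_ti(sub, reference)
        if tis.empty:
            warnings.warn(f"no usable experiments at pathway={pathway}, t={tp}")
            continue
        agg = tis.groupby("compound")["ti"].agg(["mean", "std", "count"])
        stats[(pathway, tp)] = {
            c: {"ti": r["mean"], "sd": 0.0 if np.isnan(r["std"]) else r["std"],
                "n": int(r["count"])}
            for c, r in agg.iterrows()
        }

    timepoints = sorted({tp for (_, tp) in stats})
    compounds = sorted({c for d in stats.values() for c in d})
    rows = []
    for tp in timepoints:
        go = stats.get(("Go", tp))
        barr = stats.get(("barr2", tp))
        if not go or not barr or reference not in go or reference not in barr:
            continue  # reported as a gap
        for compound in compounds:
            if compound not in go or compound not in barr:
                continue
            d_go, d_barr, bias = bias_factor(
                go[compound]["ti"], go[reference]["ti"],
                barr[compound]["ti"], barr[reference]["ti"],
            )
            se = propagate_se(
                go[compound]["sd"], go[compound]["n"],
                go[reference]["sd"], go[reference]["n"],
                barr[compound]["sd"], barr[compound]["n"],
                barr[reference]["sd"], barr[reference]["n"],
            )
            rows.append({
                "compound": compound,
                "timepoint_min": tp,
                "TI_Go": go[compound]["ti"],
                "TI_barr2": barr[compound]["ti"],
                "dTI_Go": d_go,
                "dTI_barr2": d_barr,
                "bias": bias,
                "SE_assay_Go": se["SE_assay_Go"],
                "SE_assay_barr2": se["SE_assay_barr2"],
                "SE_final": se["SE_final"],
            })
    return pd.DataFrame(rows)
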