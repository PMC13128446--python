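"""Seeded synthetic-data generators for every assay family.

Each generator draws from its own child stream of a single global seed
(derived via ``SeedSequence(seed, spawn_key=(family_index,))``), so adding
a generator never perturbs another family's output, and a fixed seed
yields byte-identical tables.  Every dataset is returned together with a
:class:`GroundTruth` echoing the generating parameters, so downstream
estimators can be tested by parameter recovery.

With all noise scales at zero each output satisfies its generating
equation exactly at every sampled point:

* BRET plates: three-parameter logistic responses on the raw BRET-ratio
  scale, with a DAMGO reference and ligand-free wells;
* kinetic BRET: 23 timepoints (2-46 min in 2-min cycles), each following
  a supplied %Emax/pEC50 trajectory per compound and pathway;
* binding kinetics: B(t) = B0 exp(-k_off t) and
  B(t) = Beq (1 - exp(-k_obs t)), k_obs = k_on L + k_off;
* APEX: compartment profiles mixed on the linear intensity scale by a
  per-timepoint nonnegative trajectory, logged, with additive batch
  offsets and Gaussian log2 noise; missing entries are missing-at-random;
* photometry: shared drift/bleach on both channels, Gaussian-bump
  transients on the sensor channel only;
* endpoint tables: logistic dose-effect latencies and per-group
  withdrawal sign counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GroundTruth",
    "BretPlateConfig",
    "KineticBretConfig",
    "BindingKineticConfig",
    "ApexConfig",
    "PhotometryConfig",
    "EndpointsConfig",
    "gen_bret_plate",
    "gen_kinetic_bret",
    "gen_binding_kinetic",
    "gen_apex_dataset",
    "gen_photometry",
    "gen_endpoints",
    "default_kinetic_trajectories",
    "KINETIC_TIMEPOINTS",
]

FAMILY_INDEX = {
    "bret_plate": 0,
    "bret_kinetic": 1,
    "binding_kinetic": 2,
    "apex": 3,
    "photometry": 4,
    "endpoints": 5,
}

#: default kinetic grid: 2-min cycles from 2 to 46 min
KINETIC_TIMEPOINTS = tuple(range(2, 47, 2))


def family_rng(seed: int, family: str) -> np.random.Generator:
    """Child random stream for one generator family under a global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(FAMILY_INDEX[family],))
    )


@dataclass
class GroundTruth:
    """Generating parameters echoed verbatim alongside each dataset."""

    family: str
    params: dict[str, Any]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"family": self.family, "params": _plain(self.params)}, fh)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _logistic(conc: np.ndarray, bottom: float, top: float, ec50: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + ec50 / conc)


# ---------------------------------------------------------------------------
# BRET plates

@dataclass
class BretPlateConfig:
    """Equilibrium BRET plate design.

    ``compounds`` maps name -> (EC50 in M, efficacy as fraction of the
    DAMGO span).  Responses sit on a raw BRET-ratio scale with baseline
    ``bottom`` and DAMGO span ``damgo_span``.
    """

    seed: int = 0
    compounds: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "DAMGO": (1.0e-8, 1.00),
        "FNZ": (5.1e-10, 1.185),
        "DFNZ": (1.66e-9, 1.165),
    })
    concentrations_M: tuple[float, ...] = tuple(
        10.0 ** e for e in np.arange(-11.0, -7.0 + 1e-9, 0.5)
    )
    n_replicates: int = 3
    bottom: float = 0.80
    damgo_span: float = 0.30
    noise_sd: float = 0.01
    n_blank_wells: int = 3

    def __post_init__(self) -> None:
        if len(self.concentrations_M) < 4:
            raise ValueError("at least 4 concentrations required")
        if any(c <= 0 for c in self.concentrations_M):
            raise ValueError("concentrations must be positive")
        if any(ec50 <= 0 for ec50, _ in self.compounds.values()):
            raise ValueError("EC50s must be positive")
        if self.n_replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def gen_bret_plate(cfg: BretPlateConfig) -> tuple[pd.DataFrame, GroundTruth]:
    rng = family_rng(cfg.seed, "bret_plate")
    rows = []
    for compound, (ec50, eff) in cfg.compounds.items():
        top = cfg.bottom + eff * cfg.damgo_span
        for rep in range(1, cfg.n_replicates + 1):
            conc = np.array(cfg.concentrations_M)
            resp = _logistic(conc, cfg.bottom, top, ec50)
            resp = resp + rng.normal(0.0, cfg.noise_sd, size=conc.shape)
            for c, r in zip(conc, resp):
                rows.append({"compound": compound, "conc_M": c,
                             "replicate": rep, "response": r})
    for rep in range(1, cfg.n_blank_wells + 1):
        rows.append({"compound": "none", "conc_M": 0.0, "replicate": rep,
                     "response": cfg.bottom + rng.normal(0.0, cfg.noise_sd)})
    gt = GroundTruth("bret_plate", {
        "compounds": {k: {"ec50_M": v[0], "efficacy_frac": v[1]}
                      for k, v in cfg.compounds.items()},
        "bottom": cfg.bottom, "damgo_span": cfg.damgo_span,
        "noise_sd": cfg.noise_sd, "seed": cfg.seed,
    })
    return pd.DataFrame(rows), gt


# ---------------------------------------------------------------------------
# Kinetic BRET

def _decay(initial: float, plateau: float, t: np.ndarray, tau: float = 8.0) -> np.ndarray:
    return plateau + (initial - plateau) * np.exp(-(t - t[0]) / tau)


def default_kinetic_trajectories(
    timepoints: tuple[float, ...] = KINETIC_TIMEPOINTS,
) -> dict[str, dict[str, dict[str, np.ndarray]]]:
    """Study-like %Emax / pEC50 trajectories per pathway and compound.

    At the G-protein pathway the two nitazenes start supramaximal
    (120.8% and 123.2% of DAMGO at 2 min) and relax to plateaus of
    111.2% and 98.4%; beta-arrestin-2 efficacies stay supramaximal.
    Potencies drift upward over the incubation as equilibration proceeds.
    """
    t = np.asarray(timepoints, dtype=float)
    ones = np.ones_like(t)
    return {
        "Go": {
            "DAMGO": {"emax_pct": 100.0 * ones, "pec50": 7.0 + 0.01 * (t - t[0])},
            "FNZ": {"emax_pct": _decay(120.8, 111.2, t), "pec50": 9.1 + 0.012 * (t - t[0])},
            "DFNZ": {"emax_pct": _decay(123.2, 98.4, t), "pec50": 9.3 + 0.015 * (t - t[0])},
        },
        "barr2": {
            "DAMGO": {"emax_pct": 100.0 * ones, "pec50": 6.8 + 0.008 * (t - t[0])},
            "FNZ": {"emax_pct": 116.0 * ones, "pec50": 9.0 + 0.010 * (t - t[0])},
            "DFNZ": {"emax_pct": 108.0 * ones, "pec50": 8.3 + 0.008 * (t - t[0])},
        },
    }


@dataclass
class KineticBretConfig:
    """Per-timepoint BRET plate series.

    ``trajectories[pathway][compound]`` holds arrays ``emax_pct`` (% of
    the reference span) and ``pec50``, one value per timepoint.
    """

    seed: int = 0
    timepoints_min: tuple[float, ...] = KINETIC_TIMEPOINTS
    trajectories: dict | None = None
    concentrations_M: tuple[float, ...] = tuple(
        10.0 ** e for e in np.arange(-12.0, -6.5 + 1e-9, 0.5)
    )
    n_replicates: int = 3
    bottom: float = 0.80
    damgo_span: float = 0.30
    noise_sd: float = 0.005

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints_min, dtype=float)
        if len(t) < 1 or np.any(np.diff(t) <= 0):
            raise ValueError("timepoint grid must be strictly increasing")
        if self.trajectories is None:
            self.trajectories = default_kinetic_trajectories(self.timepoints_min)
        for pathway, comp in self.trajectories.items():
            for name, tr in comp.items():
                for key in ("emax_pct", "pec50"):
                    if len(np.atleast_1d(tr[key])) != len(t):
                        raise ValueError(
                            f"trajectory length mismatch for {pathway}/{name}/{key}"
                        )
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def gen_kinetic_bret(cfg: KineticBretConfig) -> tuple[pd.DataFrame, GroundTruth]:
    rng = family_rng(cfg.seed, "bret_kinetic")
    conc = np.array(cfg.concentrations_M)
    rows = []
    for pathway, compounds in cfg.trajectories.items():
        for i, tp in enumerate(cfg.timepoints_min):
            for compound, tr in compounds.items():
                emax_pct = float(np.atleast_1d(tr["emax_pct"])[i])
                ec50 = 10.0 ** -float(np.atleast_1d(tr["pec50"])[i])
                top = cfg.bottom + (emax_pct / 100.0) * cfg.damgo_span
                for rep in range(1, cfg.n_replicates + 1):
                    resp = _logistic(conc, cfg.bottom, top, ec50)
                    resp = resp + rng.normal(0.0, cfg.noise_sd, size=conc.shape)
                    for c, r in zip(conc, resp):
                        rows.append({
                            "pathway": pathway, "compound": compound,
                            "timepoint_min": float(tp), "conc_M": c,
                            "replicate": rep, "response": r,
                        })
    gt = GroundTruth("bret_kinetic", {
        "timepoints_min": list(cfg.timepoints_min),
        "trajectories": cfg.trajectories,
        "bottom": cfg.bottom, "damgo_span": cfg.damgo_span,
        "noise_sd": cfg.noise_sd, "seed": cfg.seed,
    })
    return pd.DataFrame(rows), gt


# ---------------------------------------------------------------------------
# Binding kinetics

@dataclass
class BindingKineticConfig:
    seed: int = 0
    k_on: float = 7.0e8          # /M/min
    k_off: float = 0.075         # /min
    ligand_conc_M: float = 0.3e-9
    b0: float = 1000.0           # dissociation start (counts)
    beq: float = 1000.0          # association plateau
    timepoints_min: tuple[float, ...] = tuple(np.arange(0.0, 121.0, 5.0))
    n_replicates: int = 2
    noise_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off < 0:
            raise ValueError("rate constants must be nonnegative")
        if self.ligand_conc_M <= 0:
            raise ValueError("ligand concentration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def gen_binding_kinetic(cfg: BindingKineticConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    rng = family_rng(cfg.seed, "binding_kinetic")
    t = np.asarray(cfg.timepoints_min, dtype=float)
    k_obs = cfg.k_on * cfg.ligand_conc_M + cfg.k_off
    assoc_rows, dissoc_rows = [], []
    for rep in range(1, cfg.n_replicates + 1):
        assoc = cfg.beq * (1.0 - np.exp(-k_obs * t))
        dissoc = cfg.b0 * np.exp(-cfg.k_off * t)
        assoc = assoc + rng.normal(0.0, cfg.noise_sd, size=t.shape)
        dissoc = dissoc + rng.normal(0.0, cfg.noise_sd, size=t.shape)
        for tt, a, d in zip(t, assoc, dissoc):
            assoc_rows.append({"time_min": tt, "replicate": rep, "bound": a})
            dissoc_rows.append({"time_min": tt, "replicate": rep, "bound": d})
    gt = GroundTruth("binding_kinetic", {
        "k_on": cfg.k_on, "k_off": cfg.k_off, "k_obs": k_obs,
        "ligand_conc_M": cfg.ligand_conc_M, "b0": cfg.b0, "beq": cfg.beq,
        "noise_sd": cfg.noise_sd, "seed": cfg.seed,
    })
    return pd.DataFrame(assoc_rows), pd.DataFrame(dissoc_rows), gt


# ---------------------------------------------------------------------------
# APEX

from .apex import COMPARTMENTS, TIME_RANKS  # noqa: E402  (shared vocabulary)


def default_trafficking(ligand: str) -> dict[int, np.ndarray]:
    """Per-rank mixing weights over (PM, early endosome, late endo/lys,
    cytoplasm).  DAMGO and FNZ internalize briskly; DFNZ lingers at the
    plasma membrane."""
    fast = {
        1: np.array([0.85, 0.05, 0.02, 0.08]),
        2: np.array([0.70, 0.18, 0.04, 0.08]),
        3: np.array([0.45, 0.38, 0.09, 0.08]),
        4: np.array([0.30, 0.45, 0.17, 0.08]),
        5: np.array([0.20, 0.40, 0.32, 0.08]),
    }
    slow = {
        1: np.array([0.85, 0.05, 0.02, 0.08]),
        2: np.array([0.80, 0.08, 0.03, 0.09]),
        3: np.array([0.72, 0.14, 0.05, 0.09]),
        4: np.array([0.63, 0.20, 0.08, 0.09]),
        5: np.array([0.52, 0.26, 0.13, 0.09]),
    }
    return slow if ligand == "DFNZ" else fast


@dataclass
class ApexConfig:
    """Proteins x samples log2-intensity simulation.

    Reference samples scatter around fixed compartment profiles; receptor
    (MOR-APEX) samples are linear-scale mixtures of those profiles with
    weights from ``trafficking`` plus a batch offset and log2 noise.
    ``n_responders`` proteins additionally drift over the time ranks by
    ``responder_log2fc`` to exercise the interactor scoring.
    """

    seed: int = 0
    compartments: tuple[str, ...] = COMPARTMENTS
    n_markers_per_compartment: int = 15
    n_background: int = 40
    n_responders: int = 10
    marker_log2_effect: float = 3.0
    responder_log2fc: float = 2.0
    base_log2_mean: float = 20.0
    base_log2_sd: float = 1.0
    ligands: tuple[str, ...] = ("DAMGO", "FNZ", "DFNZ")
    trafficking: dict[str, dict[int, np.ndarray]] | None = None
    n_ref_replicates: int = 3
    n_mor_replicates: int = 4
    batch_offsets: tuple[float, ...] = (0.0, 0.5)
    noise_sd_log2: float = 0.25
    missing_rate: float = 0.05

    def __post_init__(self) -> None:
        if len(self.compartments) < 2:
            raise ValueError("need at least 2 compartments")
        if self.n_ref_replicates < 1 or self.n_mor_replicates < 1:
            raise ValueError("replicate counts must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing rate must be in [0, 1)")
        if len(self.batch_offsets) < 1:
            raise ValueError("at least one batch required")
        if self.trafficking is None:
            self.trafficking = {lig: default_trafficking(lig) for lig in self.ligands}
        for lig, traj in self.trafficking.items():
            for rank, w in traj.items():
                w = np.asarray(w, dtype=float)
                if np.any(w < 0):
                    raise ValueError(f"negative mixing weights for {lig} rank {rank}")
                if len(w) != len(self.compartments):
                    raise ValueError("weight vector length must match compartments")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise sd must be >= 0")


def gen_apex_dataset(cfg: ApexConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    rng = family_rng(cfg.seed, "apex")
    n_comp = len(cfg.compartments)
    proteins, marker_of = [], {}
    for ci, comp in enumerate(cfg.compartments):
        for j in range(cfg.n_markers_per_compartment):
            name = f"MK_{comp[:4].upper()}_{j:03d}"
            proteins.append(name)
            marker_of[name] = ci
    responders = [f"RSP_{j:03d}" for j in range(cfg.n_responders)]
    background = [f"BG_{j:03d}" for j in range(cfg.n_background)]
    proteins = proteins + responders + background
    n_prot = len(proteins)

    # compartment profiles on the log2 scale; markers elevated in their own
    base = rng.normal(cfg.base_log2_mean, cfg.base_log2_sd, size=n_prot)
    profiles_log2 = np.tile(base[:, None], (1, n_comp))
    for i, p in enumerate(proteins):
        if p in marker_of:
            profiles_log2[i, marker_of[p]] += cfg.marker_log2_effect
    profiles_lin = np.exp2(profiles_log2)

    sample_rows, data = [], {}

    def add_sample(sid, values_log2, **meta):
        data[sid] = values_log2
        sample_rows.append({"sample_id": sid, **meta})

    for ci, comp in enumerate(cfg.compartments):
        for rep in range(1, cfg.n_ref_replicates + 1):
            noise = rng.normal(0.0, cfg.noise_sd_log2, size=n_prot)
            add_sample(
                f"ref_{comp}_r{rep}", profiles_log2[:, ci] + noise,
                role="spatial_reference", ligand="none", time_min=np.nan,
                time_rank=0, replicate=rep, batch="b1", compartment=comp,
            )

    batches = [f"b{i+1}" for i in range(len(cfg.batch_offsets))]
    responder_idx = {proteins.index(p) for p in responders}
    for ligand in cfg.ligands:
        traj = cfg.trafficking[ligand]
        for time_min, rank in TIME_RANKS.items():
            w = np.asarray(traj[rank], dtype=float)
            mix_lin = profiles_lin @ w
            for rep in range(1, cfg.n_mor_replicates + 1):
                bi = (rep - 1) % len(batches)
                vals = np.log2(np.maximum(mix_lin, 1e-12)) + cfg.batch_offsets[bi]
                # time-responsive interactors ramp linearly in rank
                for i in responder_idx:
                    vals[i] += cfg.responder_log2fc * (rank - 1) / 4.0
                vals = vals + rng.normal(0.0, cfg.noise_sd_log2, size=n_prot)
                add_sample(
                    f"mor_{ligand}_t{time_min}_r{rep}", vals,
                    role="mor_apex", ligand=ligand, time_min=float(time_min),
                    time_rank=rank, replicate=rep, batch=batches[bi],
                    compartment="",
                )

    matrix = pd.DataFrame(data, index=proteins)
    if cfg.missing_rate > 0:
        mask = rng.random(matrix.shape) < cfg.missing_rate
        matrix = matrix.mask(mask)
    sheet = pd.DataFrame(sample_rows)
    gt = GroundTruth("apex", {
        "trafficking": {lig: {int(r): np.asarray(w).tolist() for r, w in tr.items()}
                        for lig, tr in cfg.trafficking.items()},
        "markers": {p: cfg.compartments[ci] for p, ci in marker_of.items()},
        "responders": responders,
        "responder_log2fc": cfg.responder_log2fc,
        "marker_log2_effect": cfg.marker_log2_effect,
        "batch_offsets": list(cfg.batch_offsets),
        "noise_sd_log2": cfg.noise_sd_log2,
        "missing_rate": cfg.missing_rate, "seed": cfg.seed,
    })
    return matrix, sheet, gt


# ---------------------------------------------------------------------------
# Photometry

@dataclass
class PhotometryConfig:
    """Two-channel recording: shared drift/bleach, sensor-only transients."""

    seed: int = 0
    fs_hz: float = 250.0
    duration_s: float = 600.0
    baseline_window_s: tuple[float, float] = (10.0, 170.0)
    injection_time_s: float = 180.0
    f_baseline: float = 100.0
    bleach_tau_s: float = 2000.0
    bleach_frac: float = 0.2
    drift_amp: float = 1.0
    drift_period_s: float = 240.0
    iso_scale: float = 0.6
    iso_offset: float = 10.0
    transient_times_s: tuple[float, ...] = (200.0, 260.0, 330.0, 420.0, 500.0)
    transient_amps: tuple[float, ...] = (8.0, 6.0, 9.0, 7.0, 8.0)
    transient_width_s: float = 1.5
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if any(t0 >= self.duration_s for t0 in self.transient_times_s):
            raise ValueError("transient outside the record")
        if len(self.transient_times_s) != len(self.transient_amps):
            raise ValueError("transient times and amplitudes must pair up")
        if not np.isfinite([self.bleach_tau_s, self.drift_amp]).all():
            raise ValueError("drift/bleach parameters must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def gen_photometry(cfg: PhotometryConfig):
    from .photometry import PhotometryRecording

    rng = family_rng(cfg.seed, "photometry")
    n = int(round(cfg.duration_s * cfg.fs_hz))
    t = np.arange(n) / cfg.fs_hz
    bleach = 1.0 - cfg.bleach_frac * (1.0 - np.exp(-t / cfg.bleach_tau_s))
    drift = cfg.drift_amp * np.sin(2.0 * np.pi * t / cfg.drift_period_s)
    shared = cfg.f_baseline * bleach + drift
    transients = np.zeros(n)
    for tc, amp in zip(cfg.transient_times_s, cfg.transient_amps):
        transients += amp * np.exp(-0.5 * ((t - tc) / cfg.transient_width_s) ** 2)
    f465 = shared + transients + rng.normal(0.0, cfg.noise_sd, size=n)
    f405 = cfg.iso_scale * shared + cfg.iso_offset + rng.normal(
        0.0, cfg.noise_sd * cfg.iso_scale, size=n)
    rec = PhotometryRecording(
        f_signal=f465, f_isosbestic=f405, fs_hz=cfg.fs_hz,
        baseline_window_s=cfg.baseline_window_s,
        injection_time_s=cfg.injection_time_s, animal_id=f"sim{cfg.seed}",
    )
    gt = GroundTruth("photometry", {
        "transient_times_s": list(cfg.transient_times_s),
        "transient_amps": list(cfg.transient_amps),
        "transient_width_s": cfg.transient_width_s,
        "f_baseline": cfg.f_baseline, "iso_scale": cfg.iso_scale,
        "iso_offset": cfg.iso_offset, "noise_sd": cfg.noise_sd,
        "fs_hz": cfg.fs_hz, "seed": cfg.seed,
    })
    return rec, gt


# ---------------------------------------------------------------------------
# Endpoint tables

@dataclass
class EndpointsConfig:
    seed: int = 0
    doses_mg_kg: tuple[float, ...] = (0.001, 0.003, 0.01, 0.03)
    ed50_mg_kg: float = 0.005
    baseline_latency_s: float = 10.0
    max_latency_s: float = 45.0
    n_subjects: int = 6
    latency_noise_sd: float = 1.0
    withdrawal_rates: dict[str, float] = field(default_factory=lambda: {
        "jump_attempts": 6.0, "paw_tremors": 3.0,
        "wet_dog_shakes": 2.0, "fecal_deposits": 3.0,
    })
    weight_loss_mean_g: float = 4.0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.doses_mg_kg) or self.ed50_mg_kg <= 0:
            raise ValueError("doses and ED50 must be positive")
        if self.latency_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def gen_endpoints(cfg: EndpointsConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Hot-plate latency table plus per-animal withdrawal counts."""
    rng = family_rng(cfg.seed, "endpoints")
    rows = []
    for dose in cfg.doses_mg_kg:
        frac = 1.0 / (1.0 + cfg.ed50_mg_kg / dose)
        latency = cfg.baseline_latency_s + frac * (cfg.max_latency_s - cfg.baseline_latency_s)
        for subject in range(1, cfg.n_subjects + 1):
            obs = min(latency + rng.normal(0.0, cfg.latency_noise_sd), cfg.max_latency_s)
            rows.append({
                "table": "hot_plate", "subject": f"rat{subject}",
                "dose_mg_kg": dose, "baseline_s": cfg.baseline_latency_s,
                "latency_s": obs, "max_s": cfg.max_latency_s,
            })
    for subject in range(1, cfg.n_subjects + 1):
        counts = {k: int(rng.poisson(lam)) for k, lam in cfg.withdrawal_rates.items()}
        rows.append({
            "table": "withdrawal", "subject": f"rat{subject}",
            **counts, "weight_loss_g": float(max(rng.normal(cfg.weight_loss_mean_g, 1.0), 0.0)),
        })
    gt = GroundTruth("endpoints", {k: _plain(v) for k, v in asdict(cfg).items()})
    return pd.DataFrame(rows), gt
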