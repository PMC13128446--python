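"""APEX proximity-labelling proteomics: time-course scoring and spatial
deconvolution of receptor location.

Two statistical stages operate on a proteins x samples log2-intensity
matrix with a sample sheet:

1. **Time-course scoring** — per protein, log2 intensity is modelled as a
   cubic polynomial in the *rank* of the activation timepoint (ranks
   1..5 for 0, 1, 5, 10, 30 min; ranks compress the long tail so early
   rapid changes are fit well) plus an additive batch term.  The model is
   compared with a batch-only null by a nested-model F test.  The maximum
   log2 fold change is the largest-magnitude mean change between rank 1
   and any later rank, with missing cells imputed from the fitted model.
   Interactors require max |log2FC| > log2(1.5) and p <= 0.05 (raw
   thresholds; no multiple-testing correction is applied anywhere in this
   pipeline — see docs/methods.md).

2. **Spatial deconvolution** — compartment-specific marker proteins are
   selected from the spatial-reference samples (pairwise equal-variance
   t-tests pooled across references, p < 0.005 and log2FC > 1, plus an
   abundance filter), intensities are scaled to [0, 1] per protein
   (missing -> 0), and each receptor sample is decomposed over the mean
   reference profiles by nonnegative least squares.  Three dummy columns
   of values resampled from the marker matrix absorb background so that
   true zero coefficients stay at zero; the NNLS is repeated (default
   1,000 times) with fresh dummies and the per-compartment median is
   reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

__all__ = [
    "TimeCourseScore",
    "summarize_features",
    "score_timecourse",
    "score_all",
    "call_interactors",
    "select_markers",
    "scale_intensities",
    "build_reference_system",
    "deconvolve_sample",
    "spatial_coefficients",
    "trafficking_profile",
    "COMPARTMENTS",
    "TIME_RANKS",
]

COMPARTMENTS = (
    "plasma_membrane",
    "early_endosome",
    "late_endosome_lysosome",
    "cytoplasm",
)
#: activation timepoints (min) and their rank encoding
TIME_RANKS = {0: 1, 1: 2, 5: 3, 10: 4, 30: 5}

FC_THRESHOLD = np.log2(1.5)
P_THRESHOLD = 0.05


@dataclass
class TimeCourseScore:
    protein: str
    f_stat: float
    p_value: float
    max_log2fc: float
    coefficients: np.ndarray | None = None
    rank_means: dict[int, float] = field(default_factory=dict)
    flagged: bool = False
    message: str = ""

    @property
    def is_interactor(self) -> bool:
        return (abs(self.max_log2fc) > FC_THRESHOLD) and (self.p_value <= P_THRESHOLD)


def summarize_features(features: pd.DataFrame) -> pd.DataFrame:
    """Simplified feature-to-protein summarizer.

    Sums feature (transition/peptide) intensities per protein and sample
    and drops proteins quantified by fewer than two distinct features.
    This intentionally simple roll-up stands upstream of the statistical
    stages; its boundary is documented in docs/methods.md.

    ``features`` columns: protein, feature, sample, intensity (linear).
    Returns a proteins x samples matrix of log2 summed intensities.
    """
    required = {"protein", "feature", "sample", "intensity"}
    if not required <= set(features.columns):
        raise ValueError(f"feature table needs columns {sorted(required)}")
    n_feat = features.groupby("protein")["feature"].nunique()
    keep = n_feat[n_feat >= 2].index
    sub = features[features["protein"].isin(keep)]
    mat = sub.pivot_table(index="protein", columns="sample", values="intensity",
                          aggfunc="sum")
    return np.log2(mat)


def _design_matrices(ranks: np.ndarray, batches: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(full, null) design matrices: cubic-in-rank + batch vs batch only.

    The polynomial basis is QR-orthogonalized over the observed rank grid
    for conditioning; fitted values are basis-independent.
    """
    levels = pd.unique(batches)
    # intercept + batch offsets (first batch as baseline)
    null_cols = [np.ones_like(ranks, dtype=float)]
    for lev in levels[1:]:
        null_cols.append((batches == lev).astype(float))
    x_null = np.column_stack(null_cols)
    r = ranks.astype(float)
    r_c = r - r.mean()
    poly = np.column_stack([r_c, r_c ** 2, r_c ** 3])
    q, _ = np.linalg.qr(np.column_stack([np.ones_like(r), poly]))
    x_full = np.column_stack([x_null, q[:, 1:]])
    return x_full, x_null


def _ols_rss(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return beta, float(resid @ resid), int(rank)


def score_timecourse(
    y: np.ndarray,
    time_rank: np.ndarray,
    batch: np.ndarray,
    protein: str = "",
    signed: bool = True,
) -> TimeCourseScore:
    """Score one protein's log2-intensity trend over the activation ranks.

    ``y`` may contain NaN for missing observations; those cells are
    excluded from the fit and imputed from the fitted model when forming
    per-rank means.  The F statistic compares the cubic-in-rank + batch
    model with the batch-only null:

        F = ((RSS_null - RSS_full)/d_extra) / (RSS_full/df_full)

    ``signed`` keeps the sign of the largest-magnitude change (the
    interactor threshold uses the absolute value either way).
    """
    y = np.asarray(y, dtype=float)
    ranks = np.asarray(time_rank)
    batches = np.asarray(batch)
    if not (len(y) == len(ranks) == len(batches)):
        raise ValueError("y, time_rank and batch must have equal length")
    obs = np.isfinite(y)
    if not obs.any():
        return TimeCourseScore(protein, np.nan, np.nan, np.nan, flagged=True,
                               message="all observations missing")
    if len(np.unique(ranks[obs])) < 2:
        return TimeCourseScore(protein, np.nan, np.nan, np.nan, flagged=True,
                               message="fewer than 2 distinct time ranks observed")

    x_full_all, x_null_all = _design_matrices(ranks, batches)
    x_full, x_null = x_full_all[obs], x_null_all[obs]
    yo = y[obs]
    beta_full, rss_full, rank_full = _ols_rss(x_full, yo)
    _, rss_null, rank_null = _ols_rss(x_null, yo)
    df_full = obs.sum() - rank_full
    d_extra = rank_full - rank_null
    if df_full <= 0 or d_extra <= 0:
        return TimeCourseScore(protein, np.nan, np.nan, np.nan, flagged=True,
                               message="insufficient residual degrees of freedom")
    if rss_full <= 0:
        f_stat, p_value = np.inf, 0.0
    else:
        f_stat = ((rss_null - rss_full) / d_extra) / (rss_full / df_full)
        f_stat = max(f_stat, 0.0)
        p_value = float(stats.f.sf(f_stat, d_extra, df_full))

    # per-rank means over observed values with missing cells imputed from
    # the fitted full model (imputation respects each cell's batch)
    fitted = x_full_all @ beta_full
    filled = np.where(obs, y, fitted)
    rank_means = {int(rk): float(filled[ranks == rk].mean()) for rk in np.unique(ranks)}
    base_rank = min(rank_means)
    changes = [rank_means[rk] - rank_means[base_rank]
               for rk in rank_means if rk != base_rank]
    if changes:
        max_change = changes[int(np.argmax(np.abs(changes)))]
    else:
        max_change = 0.0
    if not signed:
        max_change = abs(max_change)
    return TimeCourseScore(protein, float(f_stat), p_value, float(max_change),
                           coefficients=beta_full, rank_means=rank_means)


def score_all(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    ligand: str,
) -> pd.DataFrame:
    """Score every protein over one ligand's receptor-sample time course.

    ``matrix``: proteins x samples log2 intensities (NaN = missing).
    ``samples``: sheet with sample_id, role, ligand, time_rank, batch.
    """
    sel = samples[(samples["role"] == "mor_apex") & (samples["ligand"] == ligand)]
    if sel.empty:
        raise ValueError(f"no receptor samples for ligand {ligand!r}")
    cols = sel["sample_id"].tolist()
    ranks = sel["time_rank"].to_numpy()
    batches = sel["batch"].to_numpy()
    rows = []
    for protein, row in matrix[cols].iterrows():
        s = score_timecourse(row.to_numpy(), ranks, batches, protein=str(protein))
        rows.append({
            "protein": protein, "F": s.f_stat, "p": s.p_value,
            "max_log2fc": s.max_log2fc,
            "interactor": (not s.flagged) and s.is_interactor,
            "flagged": s.flagged, "message": s.message,
        })
    return pd.DataFrame(rows).set_index("protein")


def call_interactors(scores: pd.DataFrame) -> set[str]:
    """Proteins with max |log2FC| > log2(1.5) and p <= 0.05."""
    ok = (scores["max_log2fc"].abs() > FC_THRESHOLD) & (scores["p"] <= P_THRESHOLD)
    return set(scores.index[ok.fillna(False)])


def select_markers(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    p_threshold: float = 0.005,
    fc_threshold: float = 1.0,
    intensity_quantile: float = 0.5,
) -> pd.DataFrame:
    """Select location-specific marker proteins from the spatial references.

    A protein enters the panel when

    * for some non-redundant compartment pair the mean log2 difference
      exceeds ``fc_threshold`` with an equal-variance t-test p below
      ``p_threshold`` (residual variance pooled across *all* references
      via a one-way compartment model), and
    * its observed intensity in every replicate of at least one reference
      exceeds the global 50th percentile of all observed intensities
      (references and receptor samples jointly).

    Returns a DataFrame indexed by protein with the winning compartment
    (largest reference mean).  Receptor samples are excluded from the
    t-tests.
    """
    refs = samples[samples["role"] == "spatial_reference"]
    if refs["compartment"].nunique() < 2:
        raise ValueError("need at least 2 compartments of spatial references")
    rep_counts = refs.groupby("compartment")["sample_id"].count()
    if (rep_counts < 2).any():
        bad = rep_counts[rep_counts < 2].index.tolist()
        raise ValueError(f"compartments with <2 replicates (no variance estimate): {bad}")

    global_cutoff = float(np.nanquantile(matrix.to_numpy(dtype=float), intensity_quantile))
    comps = list(pd.unique(refs["compartment"]))
    cols_by_comp = {c: refs.loc[refs["compartment"] == c, "sample_id"].tolist()
                    for c in comps}

    records = []
    for protein, row in matrix.iterrows():
        vals = {c: row[cols_by_comp[c]].to_numpy(dtype=float) for c in comps}
        obs = {c: v[np.isfinite(v)] for c, v in vals.items()}
        usable = [c for c in comps if len(obs[c]) >= 2]
        if len(usable) < 2:
            continue
        # pooled residual variance across all references (one-way model)
        resid_ss = sum(float(((obs[c] - obs[c].mean()) ** 2).sum()) for c in usable)
        df = sum(len(obs[c]) for c in usable) - len(usable)
        if df <= 0:
            continue
        s2 = resid_ss / df
        passed = False
        for i, a in enumerate(usable):
            for b in usable[i + 1:]:
                diff = obs[a].mean() - obs[b].mean()
                se = np.sqrt(s2 * (1.0 / len(obs[a]) + 1.0 / len(obs[b])))
                if se == 0:
                    p = 0.0 if diff != 0 else 1.0
                else:
                    p = 2.0 * float(stats.t.sf(abs(diff) / se, df))
                if abs(diff) > fc_threshold and p < p_threshold:
                    passed = True
                    break
            if passed:
                break
        if not passed:
            continue
        # abundance filter: all replicates of at least one reference above cutoff
        abundant = any(
            len(vals[c]) == len(obs[c]) and np.all(obs[c] > global_cutoff)
            for c in comps
        )
        if not abundant:
            continue
        winner = max(usable, key=lambda c: obs[c].mean())
        records.append({"protein": protein, "compartment": winner})
    return pd.DataFrame(records, columns=["protein", "compartment"]).set_index("protein")


def scale_intensities(linear: pd.DataFrame) -> pd.DataFrame:
    """Scale linear intensities to [0, 1] per protein.

    Each value becomes observed/row-maximum where the row maximum is taken
    jointly over reference and receptor samples; missing values become 0.
    Proteins with zero row maximum are dropped (recorded via the returned
    frame's shrunken index).  Idempotent on already-scaled input.
    """
    arr = linear.to_numpy(dtype=float)
    if np.nanmin(np.where(np.isfinite(arr), arr, 0.0)) < 0:
        raise ValueError("linear intensities must be nonnegative")
    rowmax = np.nanmax(np.where(np.isfinite(arr), arr, -np.inf), axis=1)
    keep = rowmax > 0
    scaled = np.where(np.isfinite(arr[keep]), arr[keep], 0.0) / rowmax[keep, None]
    return pd.DataFrame(scaled, index=linear.index[keep], columns=linear.columns)


def build_reference_system(
    scaled: pd.DataFrame,
    samples: pd.DataFrame,
    panel: pd.DataFrame | list[str],
    compartments: tuple[str, ...] = COMPARTMENTS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build (F, S): per-compartment mean profiles and the marker subset.

    F has one column per compartment (declared order) holding the mean
    scaled intensity over that compartment's reference replicates, over
    all proteins; S restricts F to the marker panel rows.
    """
    panel_ids = list(panel.index) if isinstance(panel, pd.DataFrame) else list(panel)
    if not panel_ids:
        raise ValueError("marker panel is empty")
    missing = [p for p in panel_ids if p not in scaled.index]
    if missing:
        raise KeyError(f"panel proteins absent from matrix: {missing[:5]}")
    refs = samples[samples["role"] == "spatial_reference"]
    f_cols = {}
    for comp in compartments:
        cols = refs.loc[refs["compartment"] == comp, "sample_id"].tolist()
        if not cols:
            raise ValueError(f"no reference samples for compartment {comp!r}")
        f_cols[comp] = scaled[cols].mean(axis=1)
    f_mat = pd.DataFrame(f_cols, columns=list(compartments))
    s_mat = f_mat.loc[panel_ids]
    return f_mat, s_mat


def deconvolve_sample(
    y: np.ndarray,
    s_matrix: pd.DataFrame | np.ndarray,
    n_repeats: int = 1000,
    n_dummy: int = 3,
    seed: int | np.random.Generator = 0,
) -> pd.Series | np.ndarray:
    """Median-of-repeats NNLS decomposition of one sample over S.

    Per repeat, ``n_dummy`` extra columns are drawn i.i.d. uniformly with
    replacement from the entries of S, the augmented nonnegative
    least-squares problem min ||[S D] b - y||, b >= 0 is solved, and the
    coefficients of the true compartments are kept.  The per-compartment
    median over repeats is returned (a Series if S is a DataFrame).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    names = list(s_matrix.columns) if isinstance(s_matrix, pd.DataFrame) else None
    s = np.asarray(s_matrix, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.shape[0] != s.shape[0]:
        raise ValueError("sample vector not aligned to S rows")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flat = s.ravel()
    k = s.shape[1]
    coefs = np.empty((n_repeats, k))
    for i in range(n_repeats):
        dummies = rng.choice(flat, size=(s.shape[0], n_dummy), replace=True)
        beta, _ = nnls(np.hstack([s, dummies]), y)
        coefs[i] = beta[:k]
    med = np.median(coefs, axis=0)
    return pd.Series(med, index=names) if names else med


def spatial_coefficients(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    n_repeats: int = 1000,
    n_dummy: int = 3,
    seed: int = 0,
    compartments: tuple[str, ...] = COMPARTMENTS,
    panel: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """End-to-end spatial deconvolution of every receptor sample.

    ``matrix`` holds log2 intensities (NaN = missing).  Pipeline: marker
    selection (unless a panel is supplied) -> linear-scale [0,1] scaling
    -> reference system (F, S) -> per-sample median-NNLS.  One child seed
    stream per sample keeps results independent of processing order.
    """
    if panel is None:
        panel = select_markers(matrix, samples)
    linear = np.exp2(matrix)
    scaled = scale_intensities(linear)
    panel = panel.loc[panel.index.intersection(scaled.index)]
    _, s_mat = build_reference_system(scaled, samples, panel, compartments)
    mor = samples[samples["role"] == "mor_apex"].reset_index(drop=True)
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(mor))
    rows = []
    for i, rec in mor.iterrows():
        y = scaled.loc[s_mat.index, rec["sample_id"]].to_numpy(dtype=float)
        coef = deconvolve_sample(y, s_mat, n_repeats=n_repeats, n_dummy=n_dummy,
                                 seed=np.random.default_rng(streams[i]))
        row = {"sample_id": rec["sample_id"], "ligand": rec["ligand"],
               "time_rank": rec["time_rank"], "replicate": rec.get("replicate", 0)}
        row.update(coef.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def trafficking_profile(
    coefficients: pd.DataFrame,
    compartments: tuple[str, ...] = COMPARTMENTS,
) -> pd.DataFrame:
    """Replicate mean +/- sd of coefficients per ligand x time rank."""
    agg = coefficients.groupby(["ligand", "time_rank"])[list(compartments)]
    out = agg.agg(["mean", "std"])
    out.columns = [f"{comp}_{stat}" for comp, stat in out.columns]
    return out.reset_index()
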