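"""Two-channel fibre-photometry processing.

A recording pairs a sensor channel (465 nm excitation) with an isosbestic
channel (405 nm) that tracks motion artefacts and photobleaching but not
sensor activation.  Processing follows the standard chain:

1. anti-alias low-pass (10 Hz) and 10x decimation of both channels;
2. baseline model F0: a polynomial map from the isosbestic channel to the
   peak-suppressed sensor signal, estimated on a transient-poor baseline
   window and applied to the whole isosbestic trace;
3. dF/F = (F - F0)/F0;
4. transient detection by peak prominence against a per-animal threshold
   (median + k * scaled MAD of baseline dF/F, k = 2.5 by default) fixed
   across conditions;
5. slow (tonic) signal: zero-phase 0.1 Hz Butterworth low-pass and
   trapezoidal AUC in 5-min bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, sparse
from scipy.sparse.linalg import spsolve

__all__ = [
    "PhotometryRecording",
    "DffTrace",
    "TransientSet",
    "preprocess",
    "als_baseline",
    "fit_baseline",
    "compute_dff",
    "set_threshold",
    "detect_transients",
    "slow_auc",
]

MAD_SCALE = 1.4826  # scales the MAD to sigma for Gaussian noise


@dataclass
class PhotometryRecording:
    """Paired 465/405 traces on a uniform time grid."""

    f_signal: np.ndarray
    f_isosbestic: np.ndarray
    fs_hz: float
    baseline_window_s: tuple[float, float] = (0.0, 60.0)
    injection_time_s: float = 0.0
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.f_signal = np.asarray(self.f_signal, dtype=float)
        self.f_isosbestic = np.asarray(self.f_isosbestic, dtype=float)
        if self.f_signal.shape != self.f_isosbestic.shape:
            raise ValueError("channels must have equal length")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        t0, t1 = self.baseline_window_s
        if t1 <= t0:
            raise ValueError("baseline window must have positive length")
        if self.injection_time_s and t1 > self.injection_time_s:
            raise ValueError("baseline window must precede the injection")

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.f_signal)) / self.fs_hz

    def baseline_slice(self) -> slice:
        t0, t1 = self.baseline_window_s
        return slice(int(round(t0 * self.fs_hz)), int(round(t1 * self.fs_hz)))


@dataclass
class DffTrace:
    time_s: np.ndarray
    dff: np.ndarray
    f0: np.ndarray
    fs_hz: float


@dataclass
class TransientSet:
    peak_time_s: np.ndarray
    amplitude: np.ndarray
    duration_s: np.ndarray
    threshold: float
    frequency_per_min: float = field(init=False)
    window_s: float = 0.0

    def __post_init__(self) -> None:
        self.frequency_per_min = (
            len(self.peak_time_s) / (self.window_s / 60.0) if self.window_s > 0 else np.nan
        )

    def __len__(self) -> int:
        return len(self.peak_time_s)


def preprocess(rec: PhotometryRecording, cutoff_hz: float = 10.0,
               factor: int = 10) -> PhotometryRecording:
    """Anti-alias low-pass both channels then decimate.

    Requires the pre-decimation rate to be at least 20x the cutoff, and
    the cutoff to stay below the post-decimation Nyquist frequency.
    """
    if rec.fs_hz < 20.0 * cutoff_hz:
        raise ValueError("sampling rate must be >= 20x the low-pass cutoff")
    new_fs = rec.fs_hz / factor
    if cutoff_hz >= new_fs / 2.0:
        raise ValueError("cutoff at or above Nyquist after decimation")
    sos = signal.butter(4, cutoff_hz, btype="low", fs=rec.fs_hz, output="sos")
    f465 = signal.sosfiltfilt(sos, rec.f_signal)[::factor]
    f405 = signal.sosfiltfilt(sos, rec.f_isosbestic)[::factor]
    return PhotometryRecording(
        f_signal=f465, f_isosbestic=f405, fs_hz=new_fs,
        baseline_window_s=rec.baseline_window_s,
        injection_time_s=rec.injection_time_s, animal_id=rec.animal_id,
    )


def als_baseline(y: np.ndarray, lam: float = 1e7, p: float = 0.05,
                 n_iter: int = 10) -> np.ndarray:
    """Asymmetric-least-squares baseline (Whittaker smoother with
    asymmetric weights).  ``p=0.5`` gives the symmetric-weight variant;
    small ``p`` suppresses positive-going peaks so the estimate hugs the
    signal floor."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    d = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = lam * (d.T @ d)
    w = np.ones(n)
    z = y.copy()
    for _ in range(n_iter):
        wmat = sparse.diags(w, format="csc")
        z = spsolve((wmat + penalty).tocsc(), w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z


def fit_baseline(
    rec: PhotometryRecording,
    mode: str = "polynomial_rescale",
    degree: int = 1,
    als_lam: float = 1e7,
    als_p: float = 0.05,
) -> tuple[np.ndarray, dict]:
    """Estimate the F0 trace by rescaling the isosbestic channel.

    A polynomial map from isosbestic values to the sensor signal is fitted
    on the baseline window and applied to the whole isosbestic channel.
    ``mode="baseline_als"`` first suppresses residual peaks in the
    baseline-window target with an ALS floor estimate; the plain
    ``polynomial_rescale`` mode uses the raw signal as target (adequate
    when the baseline window is transient-free).

    Returns (f0, info) where ``info['flagged']`` marks a degenerate
    (constant) isosbestic paired with a varying signal.
    """
    sl = rec.baseline_slice()
    iso_base = rec.f_isosbestic[sl]
    sig_base = rec.f_signal[sl]
    if iso_base.size == 0:
        raise ValueError("baseline window is empty")
    info: dict = {"mode": mode, "degree": degree, "flagged": False}
    if mode == "baseline_als":
        target = als_baseline(sig_base, lam=als_lam, p=als_p)
    elif mode == "polynomial_rescale":
        target = sig_base
    else:
        raise ValueError(f"unknown baseline mode: {mode!r}")
    if np.std(iso_base) < 1e-12 * max(1.0, abs(np.mean(iso_base))):
        info["flagged"] = True
        if np.std(sig_base) > 0:
            warnings.warn("constant isosbestic with varying signal: F0 unreliable")
        f0 = np.full_like(rec.f_signal, float(np.mean(target)))
        info["coefficients"] = np.array([float(np.mean(target))])
        return f0, info
    coef = np.polyfit(iso_base, target, degree)
    info["coefficients"] = coef
    return np.polyval(coef, rec.f_isosbestic), info


def compute_dff(f: np.ndarray, f0: np.ndarray, fs_hz: float = 1.0) -> DffTrace:
    """Fractional fluorescence change dF/F = (F - F0)/F0, masked (NaN)
    with a warning wherever F0 <= 0."""
    f = np.asarray(f, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    if f.shape != f0.shape:
        raise ValueError("F and F0 must have equal length")
    bad = f0 <= 0
    if bad.any():
        warnings.warn(f"{bad.sum()} samples with F0 <= 0 masked")
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = np.where(bad, np.nan, (f - f0) / f0)
    return DffTrace(time_s=np.arange(len(f)) / fs_hz, dff=dff, f0=f0, fs_hz=fs_hz)


def set_threshold(baseline_dff: np.ndarray, fs_hz: float, k: float = 2.5,
                  min_duration_s: float = 60.0) -> float:
    """Per-animal prominence threshold from a baseline recording.

    threshold = median + k * (1.4826 * MAD), i.e. about k standard
    deviations above the median for Gaussian noise.  Set once per animal
    and reused across all conditions.
    """
    x = np.asarray(baseline_dff, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) / fs_hz < min_duration_s:
        raise ValueError(f"baseline must be at least {min_duration_s:.0f} s")
    med = np.median(x)
    mad = MAD_SCALE * np.median(np.abs(x - med))
    return float(med + k * mad)


def detect_transients(dff: DffTrace | np.ndarray, threshold: float,
                      fs_hz: float | None = None,
                      smooth_hz: float | None = 1.0) -> TransientSet:
    """Find fluorescence transients by peak prominence.

    The trace is first smoothed with a zero-phase low-pass at ``smooth_hz``
    (pass None to skip), matched to the ~1 s timescale of sensor
    transients, so that sample-to-sample noise does not register as
    prominent peaks while transient amplitudes are preserved.  Events are
    local maxima of the smoothed trace with prominence >= threshold;
    amplitude is the prominence, duration the full width at half
    prominence, and frequency the event count per minute of the trace.
    """
    if isinstance(dff, DffTrace):
        x, fs = dff.dff, dff.fs_hz
    else:
        if fs_hz is None:
            raise ValueError("fs_hz required when passing a bare array")
        x, fs = np.asarray(dff, dtype=float), fs_hz
    if x.size == 0:
        raise ValueError("empty trace")
    x = np.nan_to_num(x, nan=np.nanmin(x[np.isfinite(x)]) if np.isfinite(x).any() else 0.0)
    if smooth_hz is not None and smooth_hz < fs / 2.0 and len(x) > 15:
        sos = signal.butter(2, smooth_hz, btype="low", fs=fs, output="sos")
        x = signal.sosfiltfilt(sos, x)
    peaks, props = signal.find_peaks(x, prominence=threshold)
    widths = signal.peak_widths(
        x, peaks, rel_height=0.5,
        prominence_data=(props["prominences"], props["left_bases"], props["right_bases"]),
    )[0]
    return TransientSet(
        peak_time_s=peaks / fs,
        amplitude=props["prominences"],
        duration_s=widths / fs,
        threshold=float(threshold),
        window_s=len(x) / fs,
    )


def slow_auc(
    dff: DffTrace | np.ndarray,
    fs_hz: float | None = None,
    cutoff_hz: float = 0.1,
    bin_s: float = 300.0,
    t0_s: float = 0.0,
    prefiltered: bool = False,
) -> pd.DataFrame:
    """Slow-component AUC in consecutive bins.

    The trace is low-passed with a zero-phase 2nd-order Butterworth filter
    at ``cutoff_hz`` (skipped when ``prefiltered``) and the trapezoidal
    area is integrated per ``bin_s`` bin, binned from ``t0_s`` (e.g. the
    injection time).  A trailing partial bin is reported flagged.
    """
    if isinstance(dff, DffTrace):
        x, fs = dff.dff, dff.fs_hz
    else:
        if fs_hz is None:
            raise ValueError("fs_hz required when passing a bare array")
        x, fs = np.asarray(dff, dtype=float), fs_hz
    if not prefiltered:
        if cutoff_hz >= fs / 2.0:
            raise ValueError("cutoff at or above Nyquist")
        sos = signal.butter(2, cutoff_hz, btype="low", fs=fs, output="sos")
        x = signal.sosfiltfilt(sos, np.nan_to_num(x, nan=0.0))
    t = np.arange(len(x)) / fs
    start = t0_s
    rows = []
    while start < t[-1]:
        end = start + bin_s
        m = (t >= start) & (t <= end)
        if m.sum() >= 2:
            rows.append({
                "bin_start_s": start,
                "bin_end_s": min(end, float(t[-1])),
                "auc": float(np.trapezoid(x[m], t[m])),
                "partial": bool(end > t[-1] + 0.5 / fs),
            })
        start = end
    if not rows:
        raise ValueError("record shorter than one bin")
    return pd.DataFrame(rows)
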