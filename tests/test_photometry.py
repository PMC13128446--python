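"""Photometry processing: filtering, baseline, dF/F, transients, AUC."""

import numpy as np
import pandas as pd
import pytest

from morpharm import photometry as ph
from morpharm import synthetic as syn


def make_rec(f465, f405, fs, **kw):
    return ph.PhotometryRecording(f_signal=f465, f_isosbestic=f405, fs_hz=fs, **kw)


class TestPreprocess:
    FS = 250.0

    def _tone(self, freq, dur=60.0):
        t = np.arange(int(dur * self.FS)) / self.FS
        return np.sin(2 * np.pi * freq * t), t

    def test_slow_component_passes(self):
        x, _ = self._tone(0.05)
        rec = make_rec(100 + x, 60 + 0.6 * x, self.FS)
        out = ph.preprocess(rec)
        mid = slice(len(out.f_signal) // 4, -len(out.f_signal) // 4)
        amp = np.ptp(out.f_signal[mid] - 100) / 2
        assert amp > 0.99  # < 1% amplitude loss

    def test_fast_tone_attenuated(self):
        x, _ = self._tone(50.0)
        rec = make_rec(100 + x, np.full_like(x, 60.0), self.FS)
        out = ph.preprocess(rec)
        assert np.ptp(out.f_signal) / 2 < 0.1  # > 90% attenuation

    def test_constant_trace_unchanged(self):
        rec = make_rec(np.full(5000, 42.0), np.full(5000, 17.0), self.FS)
        out = ph.preprocess(rec)
        assert np.allclose(out.f_signal, 42.0)
        assert out.fs_hz == pytest.approx(25.0)

    def test_insufficient_rate_refused(self):
        rec = make_rec(np.ones(1000), np.ones(1000), 100.0)
        with pytest.raises(ValueError, match="20x"):
            ph.preprocess(rec)


class TestBaselineAndDff:
    def test_identical_channels_give_zero_dff(self):
        rng = np.random.default_rng(0)
        x = 100 + np.cumsum(rng.normal(0, 0.01, 20000))
        rec = make_rec(x, x, 100.0, baseline_window_s=(0.0, 100.0))
        f0, info = ph.fit_baseline(rec)
        dff = ph.compute_dff(rec.f_signal, f0)
        assert not info["flagged"]
        assert np.abs(dff.dff).max() < 1e-9

    def test_affine_relation_recovered(self):
        t = np.arange(30000) / 100.0
        iso = 60 + 5 * np.exp(-t / 200.0)
        sig = 2.0 * iso + 1.0
        rec = make_rec(sig, iso, 100.0, baseline_window_s=(0.0, 100.0))
        f0, _ = ph.fit_baseline(rec, degree=1)
        dff = ph.compute_dff(sig, f0)
        assert np.abs(dff.dff).max() < 1e-10

    def test_bumps_outside_baseline_window_do_not_bias_f0(self):
        t = np.arange(30000) / 100.0
        iso = 60 + 2 * np.sin(2 * np.pi * t / 120.0)
        sig = 1.5 * iso + 3.0
        bump = 20.0 * np.exp(-0.5 * ((t - 200.0) / 2.0) ** 2)
        rec = make_rec(sig + bump, iso, 100.0, baseline_window_s=(0.0, 100.0))
        f0, _ = ph.fit_baseline(rec)
        # F0 ignores the transient: residual is the bump itself
        assert np.abs((sig - f0)).max() < 1e-9

    def test_constant_isosbestic_flagged(self):
        rng = np.random.default_rng(1)
        sig = 100 + rng.normal(0, 1.0, 8000)
        rec = make_rec(sig, np.full(8000, 60.0), 100.0, baseline_window_s=(0, 60))
        with pytest.warns(UserWarning, match="constant isosbestic"):
            _, info = ph.fit_baseline(rec)
        assert info["flagged"]

    @pytest.mark.parametrize("f,f0,expected", [
        (1.0, 1.0, 0.0), (2.0, 1.0, 1.0), (1.1, 1.0, 0.1),
    ])
    def test_dff_pointwise(self, f, f0, expected):
        dff = ph.compute_dff(np.array([f]), np.array([f0]))
        assert dff.dff[0] == pytest.approx(expected)

    def test_nonpositive_f0_masked_with_warning(self):
        with pytest.warns(UserWarning, match="masked"):
            dff = ph.compute_dff(np.array([1.0, 1.0]), np.array([1.0, 0.0]))
        assert np.isnan(dff.dff[1])


class TestThreshold:
    def test_gaussian_noise_threshold_near_2p5_sigma(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.0, 0.01, 60000)
        thr = ph.set_threshold(x, fs_hz=100.0, k=2.5)
        # scaled MAD estimates sigma, so threshold ~ 2.5 sigma above median
        assert thr == pytest.approx(2.5 * 0.01, rel=0.05)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.002, 0.01, 20000)
        t1 = ph.set_threshold(x, 100.0)
        t2 = ph.set_threshold(2 * x, 100.0)
        assert t2 == pytest.approx(2 * t1, rel=1e-9)

    def test_determinism(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 0.01, 20000)
        assert ph.set_threshold(x, 100.0) == ph.set_threshold(x, 100.0)

    def test_short_baseline_refused(self):
        with pytest.raises(ValueError, match="60"):
            ph.set_threshold(np.zeros(100), fs_hz=100.0)


class TestTransients:
    FS = 25.0

    def test_flat_trace_has_no_events(self):
        events = ph.detect_transients(np.zeros(3000), threshold=0.01, fs_hz=self.FS)
        assert len(events) == 0

    def test_three_bumps_found_at_injected_times(self):
        t = np.arange(6000) / self.FS
        x = np.zeros_like(t)
        times = [60.0, 120.0, 180.0]
        for tc in times:
            x += 0.10 * np.exp(-0.5 * ((t - tc) / 1.5) ** 2)
        events = ph.detect_transients(x, threshold=0.05, fs_hz=self.FS)
        assert len(events) == 3
        assert np.allclose(events.peak_time_s, times, atol=0.2)
        assert np.all(events.amplitude >= 0.05)
        assert np.all(events.duration_s > 0)

    def test_subthreshold_bump_ignored(self):
        t = np.arange(3000) / self.FS
        x = 0.05 * np.exp(-0.5 * ((t - 60.0) / 1.5) ** 2)
        events = ph.detect_transients(x, threshold=0.1, fs_hz=self.FS)
        assert len(events) == 0

    def test_empty_trace_refused(self):
        with pytest.raises(ValueError, match="empty"):
            ph.detect_transients(np.array([]), threshold=0.1, fs_hz=self.FS)

    def test_repeated_runs_identical(self):
        rec, _ = syn.gen_photometry(syn.PhotometryConfig(seed=8, duration_s=300.0,
                                    transient_times_s=(200.0, 250.0),
                                    transient_amps=(8.0, 8.0)))
        rec = ph.preprocess(rec)
        f0, _ = ph.fit_baseline(rec)
        dff = ph.compute_dff(rec.f_signal, f0, fs_hz=rec.fs_hz)
        thr = ph.set_threshold(dff.dff[rec.baseline_slice()], rec.fs_hz)
        e1 = ph.detect_transients(dff, thr)
        e2 = ph.detect_transients(dff, thr)
        assert np.array_equal(e1.peak_time_s, e2.peak_time_s)
        assert e1.threshold == e2.threshold


class TestSlowAuc:
    FS = 10.0

    def test_constant_trace_rectangle(self):
        x = np.full(int(300 * self.FS) + 1, 0.2)
        auc = ph.slow_auc(x, fs_hz=self.FS)
        assert auc.iloc[0]["auc"] == pytest.approx(0.2 * 300.0, rel=1e-6)

    def test_fast_sinusoid_suppressed(self):
        t = np.arange(int(600 * self.FS)) / self.FS
        x = 0.5 * np.sin(2 * np.pi * 1.0 * t)  # 1 Hz >> 0.1 Hz cutoff
        auc = ph.slow_auc(x, fs_hz=self.FS)
        assert np.abs(auc["auc"]).max() < 0.5  # vs ~95 for the unfiltered bin

    def test_adjacent_bins_sum_to_union(self):
        rng = np.random.default_rng(5)
        x = np.cumsum(rng.normal(0, 0.001, int(600 * self.FS) + 1))
        two = ph.slow_auc(x, fs_hz=self.FS, bin_s=300.0)
        one = ph.slow_auc(x, fs_hz=self.FS, bin_s=600.0)
        assert two["auc"].sum() == pytest.approx(one["auc"].sum(), rel=1e-6)

    def test_partial_trailing_bin_flagged(self):
        x = np.zeros(int(450 * self.FS))
        auc = ph.slow_auc(x, fs_hz=self.FS)
        assert not auc.iloc[0]["partial"]
        assert auc.iloc[1]["partial"]

    def test_linearity_in_dff(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 0.01, int(300 * self.FS) + 1)
        a1 = ph.slow_auc(x, fs_hz=self.FS)["auc"].to_numpy()
        a3 = ph.slow_auc(3 * x, fs_hz=self.FS)["auc"].to_numpy()
        assert np.allclose(a3, 3 * a1)


class TestPipelineOnSynthetic:
    def test_no_transient_no_noise_recording_gives_zero_dff(self):
        cfg = syn.PhotometryConfig(seed=0, noise_sd=0.0, transient_times_s=(),
                                   transient_amps=(), duration_s=300.0)
        rec, _ = syn.gen_photometry(cfg)
        rec = ph.preprocess(rec)
        f0, _ = ph.fit_baseline(rec)
        dff = ph.compute_dff(rec.f_signal, f0, fs_hz=rec.fs_hz)
        assert np.nanmax(np.abs(dff.dff)) < 1e-6

    def test_injected_bumps_recovered(self):
        cfg = syn.PhotometryConfig(seed=12, duration_s=400.0,
                                   transient_times_s=(200.0, 260.0, 330.0),
                                   transient_amps=(8.0, 7.0, 9.0))
        rec, gt = syn.gen_photometry(cfg)
        rec = ph.preprocess(rec)
        f0, _ = ph.fit_baseline(rec)
        dff = ph.compute_dff(rec.f_signal, f0, fs_hz=rec.fs_hz)
        thr = ph.set_threshold(dff.dff[rec.baseline_slice()], rec.fs_hz)
        events = ph.detect_transients(dff, thr)
        assert len(events) == 3
        assert np.allclose(np.sort(events.peak_time_s),
                           gt.params["transient_times_s"], atol=1.0)
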