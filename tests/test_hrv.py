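"""Detector round-trips, R-R repair, and windowed vagal-index oracles."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.stats

import resphrv as rp
from resphrv import hrv

from conftest import match_beats


def natural_spline_oracle(x: np.ndarray, y: np.ndarray,
                          xq: np.ndarray) -> np.ndarray:
    """Independent natural cubic spline: direct tridiagonal solve for the
    second derivatives, then piecewise cubic evaluation."""
    n = x.size
    h = np.diff(x)
    A = np.zeros((n, n))
    b = np.zeros(n)
    A[0, 0] = A[-1, -1] = 1.0  # natural: zero second derivative at the ends
    for i in range(1, n - 1):
        A[i, i - 1] = h[i - 1]
        A[i, i] = 2 * (h[i - 1] + h[i])
        A[i, i + 1] = h[i]
        b[i] = 3 * ((y[i + 1] - y[i]) / h[i] - (y[i] - y[i - 1]) / h[i - 1])
    c = np.linalg.solve(A, b)
    out = np.empty_like(xq, dtype=float)
    for k, xv in enumerate(xq):
        i = np.clip(np.searchsorted(x, xv) - 1, 0, n - 2)
        dx = xv - x[i]
        bi = (y[i + 1] - y[i]) / h[i] - h[i] * (2 * c[i] + c[i + 1]) / 3
        di = (c[i + 1] - c[i]) / (3 * h[i])
        out[k] = y[i] + bi * dx + c[i] * dx ** 2 + di * dx ** 3
    return out


class TestDetector:
    def test_clean_ecg_bijective_within_10ms(self, clean_ecg_300s):
        ecg, beats, _ = clean_ecg_300s
        peaks = rp.detect_r_peaks(ecg)
        tp, fn, fp = match_beats(peaks.peak_times, beats, tol_s=0.010)
        assert fn == 0 and fp == 0
        assert tp == beats.size

    def test_flat_signal_no_peaks(self):
        sig = rp.SampledSignal(values=np.full(2000, 0.3), fs=500.0)
        peaks = rp.detect_r_peaks(sig)
        assert peaks.peak_times.size == 0

    def test_noisy_ecg_sensitivity_and_ppv(self):
        # 100 bpm template ECG with additive white noise at 20 dB SNR
        cfg = rp.SimConfig(duration_s=120.0, fs=500.0, mean_hr_bpm=100.0,
                           noise_sd_ecg=0.0, seed=21)
        beats = np.arange(0.8, 119.0, 0.6)
        clean = rp.synthesize_ecg(beats, cfg)
        snr = 10.0 ** (20.0 / 20.0)
        noise_sd = np.sqrt(np.mean(clean.values ** 2)) / snr
        rng = np.random.default_rng(22)
        noisy = rp.SampledSignal(
            values=clean.values + noise_sd * rng.standard_normal(clean.n),
            fs=500.0)
        peaks = rp.detect_r_peaks(noisy)
        tp, fn, fp = match_beats(peaks.peak_times, beats, tol_s=0.050)
        assert tp / beats.size >= 0.99
        assert tp / max(tp + fp, 1) >= 0.99

    def test_short_record_rejected(self):
        with pytest.raises(ValueError):
            rp.detect_r_peaks(rp.SampledSignal(values=np.zeros(300), fs=500.0))


class TestRRCleaning:
    def make_peaks(self, rr_ms):
        bt = np.concatenate([[0.0], np.cumsum(np.asarray(rr_ms) / 1000.0)])
        return hrv.RPeakSeries(peak_times=bt,
                               peak_indices=(bt * 500).astype(int), fs=500.0)

    def test_all_valid_identity(self):
        rr = self.make_peaks([800, 810, 790, 805, 800])
        out = rp.clean_and_interpolate_rr(rr)
        np.testing.assert_array_equal(out.rr_repaired_ms, out.rr_ms)
        assert out.valid.all()

    def test_outlier_repaired_by_natural_spline(self):
        rr_ms = [800.0, 800.0, 2000.0, 800.0, 800.0]
        out = rp.clean_and_interpolate_rr(self.make_peaks(rr_ms))
        assert list(out.valid) == [True, True, False, True, True]
        idx = np.arange(5, dtype=float)
        valid = np.array([0, 1, 3, 4], dtype=float)
        expected = natural_spline_oracle(valid,
                                         np.array([800.0, 800.0, 800.0, 800.0]),
                                         np.array([2.0]))[0]
        assert out.rr_repaired_ms[2] == pytest.approx(expected, abs=1e-9)

    def test_asymmetric_outlier_matches_oracle(self):
        rr_ms = [700.0, 760.0, 2000.0, 840.0, 900.0, 950.0]
        out = rp.clean_and_interpolate_rr(self.make_peaks(rr_ms))
        valid_idx = np.array([0, 1, 3, 4, 5], dtype=float)
        valid_y = np.array([700.0, 760.0, 840.0, 900.0, 950.0])
        expected = natural_spline_oracle(valid_idx, valid_y,
                                         np.array([2.0]))[0]
        assert out.rr_repaired_ms[2] == pytest.approx(expected, abs=1e-9)

    def test_boundary_250_inclusive(self):
        out = rp.clean_and_interpolate_rr(
            self.make_peaks([250.0, 800.0, 800.0, 800.0, 1500.0]))
        assert out.valid.all()

    def test_too_few_valid_rejected(self):
        with pytest.raises(ValueError, match="valid"):
            rp.clean_and_interpolate_rr(
                self.make_peaks([2000.0, 2000.0, 800.0, 810.0, 805.0]))

    def test_edge_invalid_held_at_nearest(self):
        out = rp.clean_and_interpolate_rr(
            self.make_peaks([2000.0, 800.0, 810.0, 805.0, 795.0, 1800.0]))
        assert out.rr_repaired_ms[0] == pytest.approx(800.0)
        assert out.rr_repaired_ms[-1] == pytest.approx(795.0)


class TestResample:
    def make_rr(self, rr_ms):
        bt = np.concatenate([[0.0], np.cumsum(np.asarray(rr_ms) / 1000.0)])
        rr = np.diff(bt) * 1000.0
        return hrv.RRSeries(beat_times=bt, rr_ms=rr,
                            valid=np.ones(rr.size, dtype=bool),
                            rr_repaired_ms=rr)

    def test_constant_series(self):
        grid, vals = rp.resample_rr(self.make_rr([800.0] * 20))
        np.testing.assert_allclose(vals, 800.0, atol=1e-9)
        np.testing.assert_allclose(np.diff(grid), 0.1, atol=1e-12)

    def test_monotone_shape_preserved(self):
        rr_ms = np.linspace(700, 1100, 25)
        grid, vals = rp.resample_rr(self.make_rr(rr_ms))
        assert np.all(np.diff(vals) >= -1e-9)

    def test_sinusoidal_modulation_rmse(self):
        # 0.25 Hz +/-50 ms modulation around 800 ms; intervals are stamped at
        # their ending beat, so construct beats satisfying
        # rr_k = f(bt_{k+1}) by fixed-point iteration
        f = lambda t: 800.0 + 50.0 * np.sin(2 * np.pi * 0.25 * t)
        bt = [0.0]
        while bt[-1] < 120.0:
            nxt = bt[-1] + 0.8
            for _ in range(30):
                nxt = bt[-1] + f(nxt) / 1000.0
            bt.append(nxt)
        bt = np.array(bt)
        rr = np.diff(bt) * 1000.0
        np.testing.assert_allclose(rr, f(bt[1:]), atol=1e-9)
        series = hrv.RRSeries(beat_times=bt, rr_ms=rr,
                              valid=np.ones(rr.size, dtype=bool),
                              rr_repaired_ms=rr)
        grid, vals = rp.resample_rr(series)
        rmse = np.sqrt(np.mean((vals - f(grid)) ** 2))
        assert rmse < 5.0


class TestIndexOracles:
    def test_rmssd_hand_values(self):
        assert rp.rmssd_window([800.0, 850.0, 800.0]) == pytest.approx(50.0)
        assert rp.rmssd_window([800.0] * 10) == 0.0
        assert rp.rmssd_window([700.0, 900.0, 700.0, 900.0]) == pytest.approx(200.0)

    def test_cvi_linear_ramp_floored(self):
        # constant successive difference -> SD1 = 0 -> floored CVI
        ramp = np.arange(800.0, 900.0, 10.0)
        assert rp.cvi_window(ramp) == pytest.approx(np.log10(1e-6))

    def test_cvi_alternating_hand_computation(self):
        rr = [700.0, 900.0, 700.0, 900.0, 700.0]
        sd1, sd2 = hrv.poincare_sd(rr)
        assert sd1 == pytest.approx(200.0 / np.sqrt(2.0))
        assert sd2 == pytest.approx(0.0, abs=1e-9)
        assert rp.cvi_window(rr) == pytest.approx(np.log10(1e-6))

    def test_sd1_rmssd_relation(self):
        rng = np.random.default_rng(3)
        rr = 800.0 + rng.normal(0.0, 30.0, 200)
        sd1, _ = hrv.poincare_sd(rr)
        assert sd1 == pytest.approx(rp.rmssd_window(rr) / np.sqrt(2.0),
                                    rel=0.05)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        rr = 800.0 + rng.normal(0.0, 25.0, 50)
        c = 1.7
        assert rp.rmssd_window(c * rr) == pytest.approx(
            c * rp.rmssd_window(rr), rel=1e-12)
        assert rp.cvi_window(c * rr) == pytest.approx(
            rp.cvi_window(rr) + 2 * np.log10(c), abs=1e-9)


class TestHFPower:
    def beats_with_modulation(self, f_mod, a, duration=60.0, rr0=0.8):
        bt = [0.0]
        while bt[-1] < duration:
            bt.append(bt[-1] + rr0 + (a / 1000.0) * np.sin(
                2 * np.pi * f_mod * bt[-1]))
        bt = np.array(bt)
        return bt[1:], np.diff(bt) * 1000.0

    def test_constant_window_floor(self):
        t = np.arange(10) * 0.8
        assert rp.hf_power_window(t, np.full(10, 800.0)) == pytest.approx(
            np.log10(1e-6))

    def test_long_window_sinusoid_power(self):
        a = 30.0
        t, rr = self.beats_with_modulation(0.25, a)
        power = 10 ** rp.hf_power_window(t, rr)
        assert power == pytest.approx(a * a / 2.0, rel=0.10)

    def test_out_of_band_modulation_rejected(self):
        a = 30.0
        t_in, rr_in = self.beats_with_modulation(0.25, a)
        t_out, rr_out = self.beats_with_modulation(0.05, a)
        p_in = 10 ** rp.hf_power_window(t_in, rr_in)
        p_out = 10 ** rp.hf_power_window(t_out, rr_out)
        assert p_out < 0.05 * p_in

    def test_in_band_modulation_never_decreases_power(self):
        rng = np.random.default_rng(5)
        bt = np.cumsum(rng.uniform(0.75, 0.85, 80))
        base = 800.0 + rng.normal(0, 5.0, bt.size)
        for a in (10.0, 30.0):
            mod = base + a * np.sin(2 * np.pi * 0.25 * bt)
            assert rp.hf_power_window(bt, mod) > rp.hf_power_window(bt, base)

    def test_batch_lomb_matches_reference(self):
        rng = np.random.default_rng(6)
        windows = []
        for _ in range(25):
            nb = rng.integers(4, 14)
            t = np.cumsum(rng.uniform(0.5, 1.1, nb))
            y = 800.0 + rng.normal(0.0, 40.0, nb)
            windows.append((t, y))
        freqs = np.arange(0.15, 0.4 + 0.005, 0.01)
        batch = hrv._batch_lomb_band_power(windows, freqs)
        for (t, y), p in zip(windows, batch):
            ref = 10 ** rp.hf_power_window(t, y) - 1e-6
            assert p == pytest.approx(ref, rel=1e-9, abs=1e-12)


class TestSlidingHRV:
    def make_rr(self, rr_ms):
        bt = np.concatenate([[0.0], np.cumsum(np.asarray(rr_ms) / 1000.0)])
        rr = np.diff(bt) * 1000.0
        return hrv.RRSeries(beat_times=bt, rr_ms=rr,
                            valid=np.ones(rr.size, dtype=bool),
                            rr_repaired_ms=rr)

    def test_constant_record_stationary_tracks(self):
        track = rp.sliding_hrv(self.make_rr([800.0] * 80))
        ok = ~np.isnan(track.rmssd_ms)
        assert ok.any()
        np.testing.assert_allclose(track.rmssd_ms[ok], 0.0, atol=1e-9)
        hf_ok = ~np.isnan(track.hf_log)
        np.testing.assert_allclose(track.hf_log[hf_ok], np.log10(1e-6),
                                   atol=1e-9)

    def test_grid_arithmetic_and_edge_missingness(self):
        rr = self.make_rr([800.0] * 100)
        track = rp.sliding_hrv(rr)
        span = rr.beat_times[-1] - np.ceil(rr.beat_times[0] / 0.1) * 0.1
        assert track.grid_times.size == int(np.floor(span / 0.1 + 1e-9)) + 1
        np.testing.assert_allclose(np.diff(track.grid_times), 0.1, atol=1e-12)
        # windows overlapping the record edges are missing
        early = track.grid_times < rr.beat_times[0] + 2.5 - 1e-6
        late = track.grid_times > rr.beat_times[-1] - 2.5 + 1e-6
        assert np.isnan(track.rmssd_ms[early]).all()
        assert np.isnan(track.rmssd_ms[late]).all()

    def test_record_shorter_than_two_windows_rejected(self):
        with pytest.raises(ValueError):
            rp.sliding_hrv(self.make_rr([800.0] * 10))

    def test_depth_coupled_rmssd_tracks_true_depth(self, coupled_subject,
                                                   coupled_result):
        track = coupled_result.track
        truth = coupled_subject.truth
        ok = ~np.isnan(track.rmssd_ms)
        idx = np.round(track.grid_times[ok] * truth.fs).astype(int)
        rho = scipy.stats.spearmanr(track.rmssd_ms[ok],
                                    truth.true_depth[idx]).statistic
        assert rho > 0

    def test_resampled_hf_input_runs(self):
        rng = np.random.default_rng(7)
        rr = self.make_rr(800.0 + rng.normal(0, 30.0, 120))
        track = rp.sliding_hrv(rr, hf_input="resampled")
        assert np.isfinite(track.hf_log[~np.isnan(track.hf_log)]).all()
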