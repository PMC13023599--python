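"""ECG R-peak detection and continuous parasympathetic HRV indices.

R peaks are found with the Pan-Tompkins algorithm (band-pass, derivative,
squaring, moving-window integration, adaptive dual thresholds with
search-back). R-R intervals outside 250-1500 ms are treated as missing and
repaired with a natural cubic spline. Three vagal indices are computed on a
sliding window represented on a uniform 0.1 s grid: log10 high-frequency
(0.15-0.40 Hz) Lomb-Scargle power, RMSSD, and the Poincare-plot cardiac
vagal index CVI = log10(SD1*SD2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.signal
from scipy.interpolate import CubicSpline, PchipInterpolator

from . import _filters
from .signals import SampledSignal

log = logging.getLogger(__name__)

RR_BOUNDS_MS = (250.0, 1500.0)
HF_BAND_HZ = (0.15, 0.40)
HF_GRID_STEP_HZ = 0.01
LOG_FLOOR_EPS = 1e-6  # ms^2, keeps degenerate windows finite on the log scale
WINDOW_S = 5.0
GRID_S = 0.1
MIN_BEATS_RMSSD = 3
MIN_BEATS_HF = 4
MIN_BEATS_CVI = 4
REFRACTORY_S = 0.2


@dataclass
class RPeakSeries:
    """Detected R-peak times (seconds) and their sample indices."""

    peak_times: np.ndarray
    peak_indices: np.ndarray
    fs: float


@dataclass
class RRSeries:
    """Beat-to-beat intervals with validity gating and spline repair.

    ``rr_ms[k]`` spans ``beat_times[k]`` to ``beat_times[k+1]``; the interval
    is timestamped at its ending beat for interpolation and windowing.
    """

    beat_times: np.ndarray
    rr_ms: np.ndarray
    valid: np.ndarray
    rr_repaired_ms: np.ndarray

    @property
    def interval_times(self) -> np.ndarray:
        return self.beat_times[1:]


@dataclass
class HRVTrack:
    """Sliding-window vagal indices on a uniform grid (NaN = missing)."""

    grid_times: np.ndarray
    hf_log: np.ndarray
    rmssd_ms: np.ndarray
    cvi: np.ndarray
    n_beats_per_window: np.ndarray
    window_s: float = WINDOW_S


def detect_r_peaks(ecg: SampledSignal) -> RPeakSeries:
    """Pan-Tompkins QRS detection.

    Stages: 5-15 Hz band-pass, five-point derivative, squaring, 150 ms
    moving-window integration, adaptive signal/noise thresholds on both the
    integrated and band-passed signals (initialized from the first 2 s),
    200 ms refractory period, and search-back at 1.66x the running R-R
    average. Reported peak times are refined to the local maximum of the
    band-passed signal.
    """
    fs = ecg.fs
    if fs < 100:
        raise ValueError("detect_r_peaks needs fs >= 100 Hz")
    if ecg.duration < 2.0:
        raise ValueError("record shorter than 2 s cannot initialize thresholds")
    x = ecg.values
    if np.ptp(x) == 0:
        log.warning("constant signal: no QRS complexes present")
        return RPeakSeries(np.empty(0), np.empty(0, dtype=int), fs)

    sos = _filters.bandpass_sos(5.0, 15.0, fs, order=3)
    bp = scipy.signal.sosfiltfilt(sos, x)
    deriv = np.convolve(bp, np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * fs / 8.0,
                        mode="same")
    sq = deriv * deriv
    mwi_n = max(1, int(round(0.15 * fs)))
    mwi = np.convolve(sq, np.ones(mwi_n) / mwi_n, mode="same")

    refractory = int(round(REFRACTORY_S * fs))
    cand, _ = scipy.signal.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        log.warning("no candidate peaks found; returning empty series")
        return RPeakSeries(np.empty(0), np.empty(0, dtype=int), fs)

    init = slice(0, int(2.0 * fs))
    spki = 0.5 * np.max(mwi[init])
    npki = 0.5 * np.mean(mwi[init])
    spkf = 0.5 * np.max(np.abs(bp[init]))
    npkf = 0.5 * np.mean(np.abs(bp[init]))
    half = int(round(0.10 * fs))

    def bp_peak(i: int) -> tuple[int, float]:
        lo, hi = max(0, i - half), min(bp.size, i + half + 1)
        j = lo + int(np.argmax(bp[lo:hi]))
        return j, bp[j]

    qrs: list[int] = []
    rr_hist: list[float] = []
    noise_cand: list[int] = []

    for i in cand:
        peaki = mwi[i]
        j, peakf = bp_peak(i)
        thr_i = npki + 0.25 * (spki - npki)
        thr_f = npkf + 0.25 * (spkf - npkf)
        is_qrs = peaki > thr_i and peakf > thr_f
        if is_qrs and qrs and (j - qrs[-1]) < refractory:
            is_qrs = False
        if is_qrs:
            # T-wave discrimination: within 360 ms of the previous QRS and
            # with a much smaller integrated peak, call it noise
            if qrs and (j - qrs[-1]) / fs < 0.36 and peaki < 0.5 * mwi[qrs[-1]]:
                is_qrs = False
        if is_qrs:
            if qrs:
                rr_hist.append((j - qrs[-1]) / fs)
                rr_hist[:] = rr_hist[-8:]
            qrs.append(j)
            spki = 0.125 * peaki + 0.875 * spki
            spkf = 0.125 * abs(peakf) + 0.875 * spkf
        else:
            noise_cand.append(i)
            npki = 0.125 * peaki + 0.875 * npki
            npkf = 0.125 * abs(peakf) + 0.875 * npkf

        # search-back when the expected beat is overdue
        if qrs and rr_hist:
            rr_avg = float(np.mean(rr_hist))
            if (i - qrs[-1]) / fs > 1.66 * rr_avg:
                window = [c for c in noise_cand
                          if qrs[-1] + refractory < c <= i
                          and mwi[c] > 0.5 * thr_i]
                if window:
                    c = max(window, key=lambda k: mwi[k])
                    jj, pf = bp_peak(c)
                    if jj - qrs[-1] >= refractory:
                        qrs.append(jj)
                        qrs.sort()
                        rr_hist.append((qrs[-1] - qrs[-2]) / fs)
                        rr_hist[:] = rr_hist[-8:]
                        spki = 0.25 * mwi[c] + 0.75 * spki
                        spkf = 0.25 * abs(pf) + 0.75 * spkf
                noise_cand = []

    idx = np.unique(np.asarray(qrs, dtype=int))
    keep = np.concatenate([[True], np.diff(idx) >= refractory]) if idx.size else \
        np.empty(0, dtype=bool)
    idx = idx[keep]
    return RPeakSeries(peak_times=idx / fs, peak_indices=idx, fs=fs)


def clean_and_interpolate_rr(peaks: RPeakSeries,
                             bounds_ms: tuple[float, float] = RR_BOUNDS_MS
                             ) -> RRSeries:
    """Gate R-R intervals to the physiological range and spline-repair them.

    Intervals outside ``bounds_ms`` (inclusive bounds) are flagged invalid
    and replaced by a natural cubic spline over beat index fitted to the
    valid intervals only. Invalid runs at the record edges are held at the
    nearest valid value.
    """
    bt = np.asarray(peaks.peak_times, dtype=float)
    if bt.size < 2:
        raise ValueError("need at least 2 peaks to form intervals")
    rr = np.diff(bt) * 1000.0
    valid = (rr >= bounds_ms[0]) & (rr <= bounds_ms[1])
    n_valid = int(valid.sum())
    if n_valid < 4:
        raise ValueError(f"only {n_valid} valid intervals; >= 4 needed for "
                         "cubic-spline repair")
    repaired = rr.copy()
    if not valid.all():
        idx = np.arange(rr.size, dtype=float)
        spline = CubicSpline(idx[valid], rr[valid], bc_type="natural")
        bad = ~valid
        inner = (idx >= idx[valid][0]) & (idx <= idx[valid][-1])
        repaired[bad & inner] = spline(idx[bad & inner])
        edge = bad & ~inner
        if edge.any():
            log.warning("invalid intervals at record edge held at nearest "
                        "valid value")
            first, last = idx[valid][0], idx[valid][-1]
            repaired[bad & (idx < first)] = rr[valid][0]
            repaired[bad & (idx > last)] = rr[valid][-1]
    return RRSeries(beat_times=bt, rr_ms=rr, valid=valid,
                    rr_repaired_ms=repaired)


def resample_rr(rr: RRSeries, grid_s: float = GRID_S
                ) -> tuple[np.ndarray, np.ndarray]:
    """Shape-preserving (PCHIP) resampling of the tachogram to a uniform grid.

    The repaired intervals, indexed by their ending beat time, are
    interpolated with a monotone piecewise cubic Hermite polynomial and
    evaluated on the ``grid_s`` grid spanning the beat support (grid times
    are integer multiples of ``grid_s``).
    """
    t = rr.interval_times
    y = rr.rr_repaired_ms
    if t.size < 2:
        raise ValueError("need at least 2 intervals to resample")
    interp = PchipInterpolator(t, y)
    start = np.ceil(t[0] / grid_s) * grid_s
    grid = np.arange(start, t[-1] + 1e-12, grid_s)
    if grid.size == 0:
        log.warning("grid outside beat support; returning empty series")
        return grid, np.empty(0)
    return grid, interp(grid)


def rmssd_window(rr_values: np.ndarray) -> float:
    """Root mean square of successive R-R differences, in ms."""
    rr_values = np.asarray(rr_values, dtype=float)
    if rr_values.size < 2:
        return np.nan
    d = rr_values[1:] - rr_values[:-1]
    return float(np.sqrt((d * d).sum() / d.size))


def poincare_sd(rr_values: np.ndarray) -> tuple[float, float]:
    """Population SD1 and SD2 of the Poincare plot of successive intervals.

    SD1/SD2 are the dispersions of the (rr_k, rr_{k+1}) scatter perpendicular
    to and along the identity line: population standard deviations of
    (rr_{k+1} -/+ rr_k)/sqrt(2).
    """
    rr_values = np.asarray(rr_values, dtype=float)
    if rr_values.size < 3:
        return np.nan, np.nan
    a, b = rr_values[:-1], rr_values[1:]
    d = (b - a) / np.sqrt(2.0)
    s = (b + a) / np.sqrt(2.0)
    n = d.size
    sd1 = float(np.sqrt(np.abs((d * d).sum() / n - (d.sum() / n) ** 2)))
    sd2 = float(np.sqrt(np.abs((s * s).sum() / n - (s.sum() / n) ** 2)))
    return sd1, sd2


def cvi_window(rr_values: np.ndarray, eps: float = LOG_FLOOR_EPS) -> float:
    """Toichi cardiac vagal index log10(SD1*SD2), floored at log10(eps)."""
    sd1, sd2 = poincare_sd(rr_values)
    if np.isnan(sd1):
        return np.nan
    prod = sd1 * sd2
    if prod <= eps:
        log.debug("degenerate Poincare window floored (SD1*SD2 = %g)", prod)
    return float(np.log10(max(prod, eps)))


def hf_power_window(beat_times: np.ndarray, rr_values: np.ndarray,
                    band_hz: tuple[float, float] = HF_BAND_HZ,
                    grid_step_hz: float = HF_GRID_STEP_HZ,
                    eps: float = LOG_FLOOR_EPS) -> float:
    """log10 high-frequency power of the tachogram via Lomb-Scargle.

    The mean-subtracted intervals at their (irregular) beat times are
    analysed with the Lomb-Scargle periodogram on a fixed frequency grid
    covering ``band_hz``; the periodogram is scaled to a one-sided spectral
    density and integrated over the band (trapezoid) to a power in ms^2,
    returned as ``log10(power + eps)``.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    rr_values = np.asarray(rr_values, dtype=float)
    if rr_values.size < 4:
        return np.nan
    y = rr_values - rr_values.mean()
    span = beat_times[-1] - beat_times[0]
    if span <= 0 or np.ptp(y) == 0:
        return float(np.log10(eps))
    freqs = np.arange(band_hz[0], band_hz[1] + grid_step_hz / 2, grid_step_hz)
    pgram = scipy.signal.lombscargle(beat_times, y, 2.0 * np.pi * freqs)
    # one-sided density: classical periodogram peak N*a^2/4 -> a^2/2 band power
    psd = pgram * 2.0 * span / rr_values.size
    power = float(np.trapezoid(psd, freqs))
    return float(np.log10(power + eps))


def _batch_lomb_band_power(windows: list[tuple[np.ndarray, np.ndarray]],
                           freqs: np.ndarray) -> np.ndarray:
    """Band power (ms^2) for many beat-domain windows at once.

    Evaluates the classical Lomb-Scargle periodogram (with the tau phase
    correction, identical to the per-window reference in
    ``hf_power_window``) for all windows simultaneously, scales each to a
    one-sided density and integrates over ``freqs``. Vectorization over
    windows only; the estimator itself is unchanged.
    """
    n_win = len(windows)
    out = np.zeros(n_win)
    if n_win == 0:
        return out
    omega = 2.0 * np.pi * freqs
    nmax = max(t.size for t, _ in windows)
    T = np.zeros((n_win, nmax))
    Y = np.zeros((n_win, nmax))
    M = np.zeros((n_win, nmax))
    ns = np.empty(n_win)
    spans = np.empty(n_win)
    flat = np.zeros(n_win, dtype=bool)
    for i, (t, y) in enumerate(windows):
        T[i, :t.size] = t
        Y[i, :t.size] = y - y.mean()
        M[i, :t.size] = 1.0
        ns[i] = t.size
        spans[i] = t[-1] - t[0]
        flat[i] = np.ptp(y) == 0 or spans[i] <= 0

    chunk = max(1, int(4e6 / (nmax * freqs.size)))
    for a in range(0, n_win, chunk):
        b = min(a + chunk, n_win)
        wt = T[a:b, :, None] * omega  # (chunk, beats, freqs)
        c = np.cos(wt) * M[a:b, :, None]
        s = np.sin(wt) * M[a:b, :, None]
        s2w = 2.0 * (c * s).sum(axis=1)
        c2w = (c * c - s * s).sum(axis=1)
        tau = 0.5 * np.arctan2(s2w, c2w)
        ct, st = np.cos(tau)[:, None, :], np.sin(tau)[:, None, :]
        cc = c * ct + s * st
        ss = s * ct - c * st
        yw = Y[a:b, :, None]
        num_c = (yw * cc).sum(axis=1)
        num_s = (yw * ss).sum(axis=1)
        den_c = (cc * cc).sum(axis=1)
        den_s = (ss * ss).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            pgram = 0.5 * (np.where(den_c > 0, num_c ** 2 / den_c, 0.0)
                           + np.where(den_s > 0, num_s ** 2 / den_s, 0.0))
        psd = pgram * (2.0 * spans[a:b] / ns[a:b])[:, None]
        out[a:b] = np.trapezoid(psd, freqs, axis=1)
    out[flat] = 0.0
    return out


def sliding_hrv(rr: RRSeries,
                window_s: float = WINDOW_S,
                grid_s: float = GRID_S,
                band_hz: tuple[float, float] = HF_BAND_HZ,
                hf_input: str = "beats") -> HRVTrack:
    """Continuous HRV indices from a centred sliding window.

    For each grid time ``t`` (multiples of ``grid_s`` spanning the beat
    support) the indices are computed from the beats inside
    ``[t - window_s/2, t + window_s/2]``. Windows that extend past the first
    or last beat, or hold fewer beats than an index's minimum, are missing
    (NaN). ``hf_input`` selects Lomb-Scargle on the irregular beat-domain
    intervals (``"beats"``, default) or on the PCHIP-resampled uniform series
    (``"resampled"``).

    With the 5 s default a window holds only a handful of beats, so one HF
    cycle (0.15 Hz) does not even complete within it; HF values at this
    window length are high-variance and should be interpreted ordinally.
    """
    if hf_input not in ("beats", "resampled"):
        raise ValueError("hf_input must be 'beats' or 'resampled'")
    bt = rr.beat_times
    it = rr.interval_times
    vals = rr.rr_repaired_ms
    if bt[-1] - bt[0] < 2 * window_s:
        raise ValueError("record must span at least twice the window length")

    start = np.ceil(bt[0] / grid_s) * grid_s
    grid = np.arange(start, bt[-1] + 1e-12, grid_s)
    half = window_s / 2.0

    if hf_input == "resampled":
        rs_grid, rs_vals = resample_rr(rr, grid_s)

    # indices of intervals whose ending beat falls inside each window
    lo = np.searchsorted(it, grid - half, side="left")
    hi = np.searchsorted(it, grid + half, side="right")
    # windows clipped by the record edges are missing
    inside = (grid - half >= bt[0] - 1e-9) & (grid + half <= bt[-1] + 1e-9)
    n_beats = np.searchsorted(bt, grid + half, side="right") - \
        np.searchsorted(bt, grid - half, side="left")

    n = grid.size
    hf = np.full(n, np.nan)
    rmssd = np.full(n, np.nan)
    cvi = np.full(n, np.nan)

    # consecutive grid points often share the same beat subset; compute each
    # unique window (keyed on interval range and beat count) only once
    keys: list[tuple[int, int, int]] = []
    key_pos: dict[tuple[int, int, int], int] = {}
    grid_key = np.full(n, -1, dtype=int)
    for k in range(n):
        if not inside[k]:
            continue
        key = (int(lo[k]), int(hi[k]), int(n_beats[k]))
        pos = key_pos.get(key)
        if pos is None:
            pos = len(keys)
            key_pos[key] = pos
            keys.append(key)
        grid_key[k] = pos

    n_keys = len(keys)
    hf_u = np.full(n_keys, np.nan)
    rmssd_u = np.full(n_keys, np.nan)
    cvi_u = np.full(n_keys, np.nan)
    hf_windows: list[tuple[np.ndarray, np.ndarray]] = []
    hf_which: list[int] = []
    for pos, (a, b, nb) in enumerate(keys):
        w = vals[a:b]
        if nb >= MIN_BEATS_RMSSD:
            rmssd_u[pos] = rmssd_window(w)
        if nb >= MIN_BEATS_CVI:
            cvi_u[pos] = cvi_window(w)
        if nb >= MIN_BEATS_HF and hf_input == "beats":
            hf_windows.append((it[a:b], w))
            hf_which.append(pos)
    if hf_input == "beats" and hf_windows:
        freqs = np.arange(band_hz[0], band_hz[1] + HF_GRID_STEP_HZ / 2,
                          HF_GRID_STEP_HZ)
        power = _batch_lomb_band_power(hf_windows, freqs)
        hf_u[hf_which] = np.log10(power + LOG_FLOOR_EPS)

    sel = grid_key >= 0
    hf[sel] = hf_u[grid_key[sel]]
    rmssd[sel] = rmssd_u[grid_key[sel]]
    cvi[sel] = cvi_u[grid_key[sel]]

    if hf_input == "resampled":
        for k in range(n):
            if grid_key[k] < 0 or n_beats[k] < MIN_BEATS_HF:
                hf[k] = np.nan
                continue
            m = (rs_grid >= grid[k] - half) & (rs_grid <= grid[k] + half)
            hf[k] = hf_power_window(rs_grid[m], rs_vals[m], band_hz)

    return HRVTrack(grid_times=grid, hf_log=hf, rmssd_ms=rmssd, cvi=cvi,
                    n_beats_per_window=n_beats.astype(float),
                    window_s=window_s)


def whole_record_indices(rr: RRSeries,
                         band_hz: tuple[float, float] = HF_BAND_HZ) -> dict:
    """HF, RMSSD and CVI computed once over the entire recording."""
    return {
        "hf_log": hf_power_window(rr.interval_times, rr.rr_repaired_ms, band_hz),
        "rmssd_ms": rmssd_window(rr.rr_repaired_ms),
        "cvi": cvi_window(rr.rr_repaired_ms),
    }
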