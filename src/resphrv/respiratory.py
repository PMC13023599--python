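"""Respiratory preprocessing and Hilbert decomposition.

The belt signal is reduced to a quasi-monocomponent waveform (drift below
0.01 Hz removed, noise above 2 Hz removed, then low-passed at 0.75 Hz) and
decomposed via the analytic signal into instantaneous amplitude (respiratory
depth), a monotonicity-corrected instantaneous phase, and instantaneous
frequency (respiratory rate). The sign of the frequency is additionally
inverted so that, like depth, larger values are expected to associate
positively with parasympathetic indices (slower breathing = higher value).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.signal
from scipy.interpolate import make_smoothing_spline

from . import _filters
from .signals import SampledSignal

log = logging.getLogger(__name__)

DRIFT_CUTOFF_HZ = 0.01
NOISE_CUTOFF_HZ = 2.0
RESP_LOWPASS_HZ = 0.75
DEFAULT_GUARD_S = 10.0
#: minimum record length for the 0.01 Hz drift estimate to be meaningful
MIN_RECORD_S = 30.0


@dataclass
class RespDecomposition:
    """Time-aligned respiratory measures derived from one belt recording.

    All arrays share the input length and sampling rate. ``rate_inverted``
    is exactly ``-frequency``. ``guard_s`` is the edge width (seconds) that
    downstream correlation stages should exclude.
    """

    fs: float
    preprocessed: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray
    frequency: np.ndarray
    rate_inverted: np.ndarray
    guard_s: float = DEFAULT_GUARD_S

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.preprocessed.size) / self.fs

    def interior(self) -> np.ndarray:
        """Boolean mask excluding the guard bands at both record edges."""
        n = self.preprocessed.size
        g = int(round(self.guard_s * self.fs))
        mask = np.zeros(n, dtype=bool)
        if 2 * g < n:
            mask[g:n - g] = True
        return mask


def _slow_trend(x: np.ndarray, fs: float, cutoff: float = DRIFT_CUTOFF_HZ) -> np.ndarray:
    """Estimate the sub-``cutoff`` baseline drift of an oscillatory signal.

    Breath-period block means (one block per dominant respiratory cycle, so
    respiratory-band content largely cancels) are fitted with a penalized
    smoothing spline whose penalty places the half-power point at ``cutoff``
    (fourth-order rolloff). The block series is extended by point reflection
    about robust endpoint levels so the boundary behaves like the interior,
    and the first/last blocks (filter-transient prone) are excluded from the
    fit. This realizes a zero-phase 0.01 Hz high-pass without the minute-long
    edge transients a recursive filter would have at this corner frequency.
    """
    n = x.size
    t = np.arange(n) / fs
    # dominant respiratory frequency from a periodogram of the signal
    # decimated to ~4 Hz (plenty for a <= 0.75 Hz rhythm)
    dec = max(1, int(fs // 4))
    nd = n // dec * dec
    xd = x[:nd].reshape(-1, dec).mean(axis=1) if dec > 1 else x
    f, p = scipy.signal.periodogram(xd - xd.mean(), fs / dec)
    band = (f >= 0.05) & (f <= RESP_LOWPASS_HZ)
    f0 = f[band][np.argmax(p[band])] if np.any(band) and p[band].max() > 0 else 0.25
    step = max(1, int(round(fs / max(f0, 0.05))))

    nb = n // step
    if nb < 8:
        step = max(1, n // 8)
        nb = n // step
    m = nb * step
    xb = x[:m].reshape(nb, step).mean(axis=1)
    tb = t[:m].reshape(nb, step).mean(axis=1)
    if nb > 8:  # drop transient-contaminated edge blocks
        xb, tb = xb[1:-1], tb[1:-1]
    dt = step / fs

    L = min(xb.size - 1, max(4, int(round(120.0 / dt))))
    K = min(xb.size, 10)
    c0 = np.polyval(np.polyfit(tb[:K], xb[:K], 1), tb[0])
    c1 = np.polyval(np.polyfit(tb[-K:], xb[-K:], 1), tb[-1])
    xe = np.concatenate([2 * c0 - xb[1:L + 1][::-1], xb, 2 * c1 - xb[-L - 1:-1][::-1]])
    te = np.concatenate([2 * tb[0] - tb[1:L + 1][::-1], tb, 2 * tb[-1] - tb[-L - 1:-1][::-1]])

    lam = 1.0 / (dt * (2.0 * np.pi * cutoff) ** 4)
    return make_smoothing_spline(te, xe, lam=lam)(t)


def preprocess_respiration(raw: SampledSignal,
                           guard_s: float = DEFAULT_GUARD_S) -> SampledSignal:
    """Band-limit a raw belt signal to a quasi-monocomponent waveform.

    Removes the mean and sub-0.01 Hz drift, low-passes at 2 Hz, then at
    0.75 Hz (both 4th-order zero-phase Butterworth). Output has the same
    length and sampling rate; edge effects are confined to ``guard_s``.
    """
    if raw.duration < MIN_RECORD_S:
        raise ValueError(
            f"record of {raw.duration:.1f} s is too short to preprocess; "
            f"at least {MIN_RECORD_S:.0f} s are needed for the {DRIFT_CUTOFF_HZ} Hz "
            "drift removal to settle"
        )
    x = raw.values - raw.values.mean()
    x = x - _slow_trend(x, raw.fs)
    for corner in (NOISE_CUTOFF_HZ, RESP_LOWPASS_HZ):
        sos = _filters.lowpass_sos(corner, raw.fs)
        x = scipy.signal.sosfiltfilt(sos, x, padtype="even")
    return SampledSignal(values=x, fs=raw.fs, t0=raw.t0, name=raw.name)


def compute_analytic(signal: SampledSignal) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous amplitude and unwrapped phase of the analytic signal."""
    x = signal.values
    if not np.any(x):
        log.warning("all-zero signal: amplitude set to 0, phase to 0 by convention")
        return np.zeros_like(x), np.zeros_like(x)
    analytic = scipy.signal.hilbert(x)
    amplitude = np.abs(analytic)
    raw_phase = np.unwrap(np.angle(analytic))
    return amplitude, raw_phase


def _repair_decreases(phase: np.ndarray) -> np.ndarray:
    """Linearly interpolate across every decreasing run of the phase.

    Each dip is bridged from the sample where the phase stops increasing (the
    local maximum preceding the run) to the first later sample that recovers
    to at least that level, i.e. the bracketing extrema of the dip.
    """
    p = phase.copy()
    n = p.size
    i = 0
    while i < n - 1:
        if p[i + 1] < p[i]:
            j = i + 1
            while j < n and p[j] < p[i]:
                j += 1
            if j >= n:
                p[i + 1:] = p[i]  # dip never recovers: hold level to the end
                break
            p[i:j + 1] = np.linspace(p[i], p[j], j - i + 1)
            i = j
        else:
            i += 1
    return p


def correct_phase(raw_phase: np.ndarray, fs: float, n_iter: int = 10,
                  lowpass_hz: float = RESP_LOWPASS_HZ) -> np.ndarray:
    """Enforce a monotone phase course.

    Runs up to ``n_iter`` iterations of {bridge decreasing segments by
    linear interpolation between their bracketing extrema; low-pass at
    ``lowpass_hz``}. The low-pass is applied to the phase increments and the
    result re-integrated, which smooths the interpolation kinks without
    re-introducing drift in the overall slope. An iteration that finds no
    decreasing segment is a no-op, so the procedure is at a fixpoint once
    the phase is monotone (monotone input is returned unchanged). A final
    bridging pass guarantees the output is non-decreasing to within
    numerical tolerance.
    """
    p = np.asarray(raw_phase, dtype=float).copy()
    sos = _filters.lowpass_sos(lowpass_hz, fs)
    for _ in range(n_iter):
        if p.size < 2 or np.min(np.diff(p)) >= 0:
            break
        p = _repair_decreases(p)
        inc_f = scipy.signal.sosfiltfilt(sos, np.diff(p), padtype="even")
        p = p[0] + np.concatenate([[0.0], np.cumsum(inc_f)])
    residual = np.min(np.diff(p), initial=0.0)
    if residual < 0:
        p = _repair_decreases(p)
    return p


def instantaneous_frequency(phase: np.ndarray, fs: float) -> np.ndarray:
    """Phase derivative over 2*pi in Hz.

    Central differences in the interior, one-sided at the endpoints (exact
    for linear phase).
    """
    return np.gradient(np.asarray(phase, dtype=float)) * fs / (2.0 * np.pi)


def decompose_respiration(raw: SampledSignal,
                          guard_s: float = DEFAULT_GUARD_S,
                          preprocess: bool = True) -> RespDecomposition:
    """Full decomposition: preprocess, analytic signal, phase correction,
    instantaneous frequency, and the sign-inverted rate."""
    pre = preprocess_respiration(raw, guard_s=guard_s) if preprocess else raw
    amplitude, raw_phase = compute_analytic(pre)
    phase = correct_phase(raw_phase, pre.fs)
    frequency = instantaneous_frequency(phase, pre.fs)
    return RespDecomposition(
        fs=pre.fs,
        preprocessed=pre.values,
        amplitude=amplitude,
        phase=phase,
        frequency=frequency,
        rate_inverted=-frequency,
        guard_s=guard_s,
    )
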