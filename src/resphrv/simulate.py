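"""Synthetic cardiorespiratory cohort generator.

Produces paired respiratory-belt and ECG channels with known ground truth so
every downstream stage (envelope/rate decomposition, QRS detection, sliding
HRV, cohort statistics) can be verified end to end. Respiration is an
amplitude- and frequency-modulated oscillation with slowly drifting depth and
rate plus occasional deep breaths (sighs); beats come from an integral pulse
frequency modulation (IPFM) model whose vagal modulation can be coupled, with
configurable gain, to respiratory depth and/or rate; ECG morphology is a
fixed template train.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace

import numpy as np
import scipy.signal

from . import _filters
from .signals import SampledSignal

log = logging.getLogger(__name__)

#: low-pass corner (Hz) of the slow envelope processes driving depth and rate
ENVELOPE_BANDWIDTH_HZ = 0.05
#: low-pass corner (Hz) of the respiration-independent vagal modulation
INTRINSIC_BANDWIDTH_HZ = 0.5
#: saturation of the RSA modulation amplitude (fraction of mean heart rate);
#: keeps sigh-driven excursions of the coupled envelope physiological
RSA_AMP_CAP = 0.75


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated recording.

    Units are given per field; ``seed`` makes the whole simulation a pure
    function of the configuration.
    """

    duration_s: float = 300.0
    fs: float = 500.0
    base_breath_rate_hz: float = 0.25
    breath_rate_sd_hz: float = 0.03
    base_depth: float = 1.0
    depth_sd: float = 0.25
    sigh_rate_per_min: float = 0.5
    mean_hr_bpm: float = 70.0
    rsa_gain_depth: float = 0.0
    rsa_gain_rate: float = 0.0
    #: baseline RSA modulation amplitude (dimensionless fraction of heart rate)
    rsa_base: float = 0.1
    #: sd of the respiration-independent vagal modulation (dimensionless)
    intrinsic_hrv_sd: float = 0.05
    noise_sd_ecg: float = 0.05
    noise_sd_resp: float = 0.02
    #: amplitude (a.u.) of the sub-0.01 Hz baseline drift added to respiration
    drift_amplitude: float = 0.3
    drift_freq_hz: float = 0.004
    seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"SimConfig.{f.name} must be finite, got {v!r}")
        if self.duration_s <= 0:
            raise ValueError("SimConfig.duration_s must be > 0")
        if self.fs <= 0:
            raise ValueError("SimConfig.fs must be > 0")
        if not 30.0 < self.mean_hr_bpm < 200.0:
            raise ValueError("SimConfig.mean_hr_bpm must lie in (30, 200)")
        if not 0.05 < self.base_breath_rate_hz < 0.75:
            raise ValueError(
                "SimConfig.base_breath_rate_hz must lie in (0.05, 0.75) so the "
                "simulated rhythm survives the 0.75 Hz low-pass"
            )
        for name in ("breath_rate_sd_hz", "depth_sd", "sigh_rate_per_min",
                     "noise_sd_ecg", "noise_sd_resp", "intrinsic_hrv_sd",
                     "drift_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"SimConfig.{name} must be >= 0")
        if self.base_depth <= 0:
            raise ValueError("SimConfig.base_depth must be > 0")


@dataclass
class GroundTruth:
    """True latent processes of one simulated subject, on the sample grid."""

    fs: float
    true_depth: np.ndarray
    true_rate: np.ndarray
    true_phase: np.ndarray
    true_beat_times: np.ndarray | None = None
    true_vagal_modulation: np.ndarray | None = None

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.true_depth.size) / self.fs


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _slow_process(rng: np.random.Generator, n: int, fs: float,
                  corner_hz: float) -> np.ndarray:
    """Band-limited unit-variance Gaussian process (z-scored over the record).

    White noise is generated with padding of a few filter time constants on
    each side and trimmed after filtering, so edge transients never reach
    the returned segment.
    """
    pad = int(round(4.0 / corner_hz * fs))
    white = rng.standard_normal(n + 2 * pad)
    sos = _filters.lowpass_sos(corner_hz, fs)
    smooth = scipy.signal.sosfiltfilt(sos, white)[pad:pad + n]
    return _zscore(smooth)


def simulate_respiration(config: SimConfig) -> tuple[SampledSignal, GroundTruth]:
    """Simulate a respiratory-belt channel.

    The waveform is ``depth(t) * cos(phi(t)) + drift + noise`` where ``depth``
    is a positive slowly varying envelope (floored at 10% of ``base_depth``,
    with transient sigh boosts) and ``d(phi)/dt = 2*pi*rate(t)`` for a slowly
    varying rate centred on ``base_breath_rate_hz``.
    """
    n = int(round(config.duration_s * config.fs))
    if n < 2:
        raise ValueError("duration_s * fs must give at least 2 samples")
    t = np.arange(n) / config.fs

    rng_depth = np.random.default_rng([config.seed, 11])
    rng_rate = np.random.default_rng([config.seed, 12])
    rng_misc = np.random.default_rng([config.seed, 13])

    depth = config.base_depth + config.depth_sd * (
        _slow_process(rng_depth, n, config.fs, ENVELOPE_BANDWIDTH_HZ)
        if config.depth_sd > 0 else np.zeros(n)
    )

    # sighs: Poisson-distributed transient boosts of the envelope
    if config.sigh_rate_per_min > 0:
        n_sighs = rng_misc.poisson(config.sigh_rate_per_min * config.duration_s / 60.0)
        sigh_times = rng_misc.uniform(0.0, config.duration_s, size=n_sighs)
        sigh_width_s = 2.0
        for tc in sigh_times:
            depth = depth + config.base_depth * np.exp(
                -0.5 * ((t - tc) / sigh_width_s) ** 2
            )
    depth = np.maximum(depth, 0.1 * config.base_depth)

    rate = config.base_breath_rate_hz + config.breath_rate_sd_hz * (
        _slow_process(rng_rate, n, config.fs, ENVELOPE_BANDWIDTH_HZ)
        if config.breath_rate_sd_hz > 0 else np.zeros(n)
    )
    rate = np.clip(rate, 0.051, 0.749)

    phase = 2.0 * np.pi * np.cumsum(rate) / config.fs
    phase += rng_misc.uniform(0.0, 2.0 * np.pi)

    drift = config.drift_amplitude * np.sin(
        2.0 * np.pi * config.drift_freq_hz * t + rng_misc.uniform(0.0, 2.0 * np.pi)
    )
    noise = (config.noise_sd_resp * rng_misc.standard_normal(n)
             if config.noise_sd_resp > 0 else 0.0)

    values = depth * np.cos(phase) + drift + noise
    resp = SampledSignal(values=values, fs=config.fs, name="resp")
    truth = GroundTruth(fs=config.fs, true_depth=depth, true_rate=rate,
                        true_phase=phase)
    return resp, truth


def simulate_beat_times(truth: GroundTruth, config: SimConfig) -> np.ndarray:
    """Emit beat times from an IPFM model driven by vagal modulation.

    The instantaneous heart rate is ``(1 + m(t)) * HR0/60`` with

    ``m(t) = clip(rsa_base + g_d*z(depth) + g_r*z(rate), 0, cap) *
             sin(phi_resp) + intrinsic(t)``

    so the within-breath RSA amplitude tracks respiratory depth and/or rate
    (z-scored slow envelopes) while ``intrinsic`` is band-limited modulation
    independent of respiration. The amplitude bracket is clipped to
    ``[0, RSA_AMP_CAP]``: it cannot go negative (which would flip the RSA
    phase for shallow breaths) and saturates for extreme sigh-driven
    excursions. Beats occur where the integrated rate crosses successive
    integers.
    """
    n = truth.true_depth.size
    t = truth.times

    rsa_amp = (config.rsa_base
               + config.rsa_gain_depth * _zscore(truth.true_depth)
               + config.rsa_gain_rate * _zscore(truth.true_rate))
    rsa_amp = np.clip(rsa_amp, 0.0, RSA_AMP_CAP)
    m = rsa_amp * np.sin(truth.true_phase)
    if config.intrinsic_hrv_sd > 0:
        rng = np.random.default_rng([config.seed, 21])
        m = m + config.intrinsic_hrv_sd * _slow_process(
            rng, n, config.fs, INTRINSIC_BANDWIDTH_HZ)

    peak = np.max(np.abs(m)) if n else 0.0
    if peak >= 1.0:
        which = ("rsa_gain_depth" if config.rsa_gain_depth >= config.rsa_gain_rate
                 else "rsa_gain_rate")
        raise ValueError(
            f"vagal modulation |m| reached {peak:.3f} >= 1; reduce {which} "
            "(or rsa_base / intrinsic_hrv_sd)"
        )

    lam = (1.0 + m) * (config.mean_hr_bpm / 60.0)
    integral = np.cumsum(lam) / config.fs
    n_beats = int(np.floor(integral[-1]))
    if n_beats == 0:
        return np.empty(0)
    beat_times = np.interp(np.arange(1, n_beats + 1, dtype=float), integral, t)
    truth.true_beat_times = beat_times
    truth.true_vagal_modulation = m
    return beat_times


def synthesize_ecg(beat_times: np.ndarray, config: SimConfig) -> SampledSignal:
    """Render a template-based ECG with QRS complexes at ``beat_times``.

    Each beat contributes a narrow positive R wave (Gaussian, ~20 ms width,
    unit amplitude) plus smaller P and T bumps; white noise of sd
    ``noise_sd_ecg`` is added.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size and np.any(np.diff(beat_times) <= 0):
        raise ValueError("beat_times must be strictly increasing")
    if beat_times.size and (beat_times[0] < 0 or beat_times[-1] > config.duration_s):
        raise ValueError("beat_times must lie within [0, duration_s]")
    if beat_times.size > 1 and np.min(np.diff(beat_times)) < 0.2:
        log.warning("beat spacing below 200 ms refractory period; the QRS "
                    "detector may merge beats")

    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    ecg = np.zeros(n)
    # (delay s, amplitude a.u., width sigma s) for P, R, T waves
    waves = [(-0.18, 0.10, 0.04), (0.0, 1.0, 0.01), (0.25, 0.15, 0.07)]
    for delay, amp, sigma in waves:
        half = int(np.ceil(5 * sigma * config.fs))
        for tb in beat_times:
            c = int(round((tb + delay) * config.fs))
            lo, hi = max(0, c - half), min(n, c + half + 1)
            if lo >= hi:
                continue
            ecg[lo:hi] += amp * np.exp(
                -0.5 * ((t[lo:hi] - tb - delay) / sigma) ** 2)
    if config.noise_sd_ecg > 0:
        rng = np.random.default_rng([config.seed, 31])
        ecg = ecg + config.noise_sd_ecg * rng.standard_normal(n)
    return SampledSignal(values=ecg, fs=config.fs, name="ecg")


@dataclass
class SubjectSim:
    """One simulated participant: paired channels plus latent ground truth."""

    subject_id: str
    config: SimConfig
    resp: SampledSignal
    ecg: SampledSignal
    truth: GroundTruth


def simulate_subject(config: SimConfig, subject_id: str = "S00") -> SubjectSim:
    """Run the three generator stages for a single configuration."""
    resp, truth = simulate_respiration(config)
    beats = simulate_beat_times(truth, config)
    ecg = synthesize_ecg(beats, config)
    return SubjectSim(subject_id=subject_id, config=config, resp=resp,
                      ecg=ecg, truth=truth)


SCENARIOS = ("depth-coupled", "rate-coupled", "null")
#: shipped default coupling gain used by the named scenarios
DEFAULT_SCENARIO_GAIN = 0.2


def simulate_cohort(n_subjects: int,
                    config_template: SimConfig | None = None,
                    scenario: str = "depth-coupled",
                    master_seed: int | None = None,
                    scenario_gain: float = DEFAULT_SCENARIO_GAIN,
                    ) -> list[SubjectSim]:
    """Simulate a cohort with per-subject physiological jitter.

    Per-subject seeds are derived from ``master_seed`` via a counter-based
    ``SeedSequence`` scheme, so subject ``i`` is reproducible in isolation.
    ``scenario`` sets the coupling gains: ``"depth-coupled"`` -> (g, 0),
    ``"rate-coupled"`` -> (0, g), ``"null"`` -> (0, 0) with the baseline RSA
    amplitude also zeroed so cardiac variability is independent of respiration
    by construction.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}, got {scenario!r}")
    template = config_template if config_template is not None else SimConfig()
    if master_seed is None:
        master_seed = template.seed

    subjects = []
    for i in range(n_subjects):
        ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(i,))
        rng = np.random.default_rng(ss)
        seed_i = int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))

        g_d, g_r = {
            "depth-coupled": (scenario_gain, 0.0),
            "rate-coupled": (0.0, scenario_gain),
            "null": (0.0, 0.0),
        }[scenario]
        cfg = replace(
            template,
            seed=seed_i,
            rsa_gain_depth=g_d,
            rsa_gain_rate=g_r,
            rsa_base=0.0 if scenario == "null" else
                     template.rsa_base * rng.lognormal(0.0, 0.25),
            mean_hr_bpm=float(np.clip(rng.normal(template.mean_hr_bpm, 7.0),
                                      50.0, 110.0)),
            base_breath_rate_hz=float(np.clip(
                rng.normal(template.base_breath_rate_hz, 0.03), 0.15, 0.35)),
            base_depth=template.base_depth * rng.lognormal(0.0, 0.2),
            intrinsic_hrv_sd=template.intrinsic_hrv_sd * rng.lognormal(0.0, 0.3),
        )
        subjects.append(simulate_subject(cfg, subject_id=f"S{i:02d}"))
    return subjects
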