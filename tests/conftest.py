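"""Shared fixtures: deterministic synthetic signals and analyzed subjects."""

from __future__ import annotations

import numpy as np
import pytest

import resphrv as rp

FS = 500.0


@pytest.fixture(scope="session")
def tone_300s():
    """Pure 0.25 Hz unit sinusoid, 300 s at 500 Hz."""
    t = np.arange(0, 300, 1 / FS)
    return rp.SampledSignal(values=np.sin(2 * np.pi * 0.25 * t), fs=FS,
                            name="resp")


@pytest.fixture(scope="session")
def coupled_subject():
    """One depth-coupled simulated participant (300 s at 500 Hz)."""
    cfg = rp.SimConfig(duration_s=300.0, fs=FS, rsa_gain_depth=0.2, seed=3)
    return rp.simulate_subject(cfg)


@pytest.fixture(scope="session")
def coupled_result(coupled_subject):
    """Full pipeline output for the depth-coupled participant."""
    return rp.analyze_subject(coupled_subject.resp, coupled_subject.ecg,
                              rp.RunConfig(), subject_id="fix")


@pytest.fixture(scope="session")
def clean_ecg_300s():
    """Noise-free template ECG at 60 bpm with known beat times."""
    cfg = rp.SimConfig(duration_s=300.0, fs=FS, mean_hr_bpm=60.0,
                       rsa_base=0.0, rsa_gain_depth=0.0, rsa_gain_rate=0.0,
                       intrinsic_hrv_sd=0.0, noise_sd_ecg=0.0, seed=5)
    beats = np.arange(1.0, 299.0, 1.0)
    ecg = rp.synthesize_ecg(beats, cfg)
    return ecg, beats, cfg


def match_beats(detected: np.ndarray, truth: np.ndarray,
                tol_s: float) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected to true beats within tol_s.

    Returns (true positives, false negatives, false positives).
    """
    used = np.zeros(truth.size, dtype=bool)
    tp = 0
    for d in detected:
        idx = np.argmin(np.abs(truth - d))
        if not used[idx] and abs(truth[idx] - d) <= tol_s:
            used[idx] = True
            tp += 1
    return tp, int(truth.size - tp), int(detected.size - tp)
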