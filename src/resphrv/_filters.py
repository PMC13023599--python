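"""Cached Butterworth designs (filter design is pure in its arguments)."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import scipy.signal


@lru_cache(maxsize=64)
def butter_sos(order: int, wn: float | tuple[float, float], btype: str
               ) -> np.ndarray:
    return scipy.signal.butter(order, wn, btype, output="sos")


def lowpass_sos(corner_hz: float, fs: float, order: int = 4) -> np.ndarray:
    return butter_sos(order, min(corner_hz / (fs / 2.0), 0.99), "low")


def bandpass_sos(lo_hz: float, hi_hz: float, fs: float,
                 order: int = 4) -> np.ndarray:
    return butter_sos(order, (lo_hz / (fs / 2.0),
                              min(hi_hz / (fs / 2.0), 0.99)), "bandpass")
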