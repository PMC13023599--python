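"""Core sampled-signal container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled 1-D physiological channel.

    Parameters
    ----------
    values : ndarray
        Sample values in arbitrary units.
    fs : float
        Sampling rate in Hz. Must be positive.
    t0 : float
        Time of the first sample in seconds.
    name : str
        Channel label (e.g. ``"resp"`` or ``"ecg"``).
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("values must be a 1-D array")
        if values.size < 2:
            raise ValueError("signal needs at least 2 samples")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError("fs must be a positive finite number")
        if not np.all(np.isfinite(values)):
            n_bad = int(np.sum(~np.isfinite(values)))
            first = int(np.flatnonzero(~np.isfinite(values))[0])
            raise ValueError(
                f"signal contains {n_bad} non-finite samples (first at index {first})"
            )

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Record span in seconds (first to last sample)."""
        return (self.n - 1) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs
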