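"""Figure builders mirroring the standard report layout."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from . import stats  # noqa: E402

_MEASURE_COLORS = {"waveform": "tab:green", "amplitude": "tab:red",
                   "rate_inverted": "tab:blue"}


def decomposition_traces(decomp, path: str | Path) -> None:
    """Waveform + amplitude, corrected phase, and instantaneous frequency."""
    t = decomp.times
    fig, axes = plt.subplots(3, 1, figsize=(10, 7), sharex=True)
    axes[0].plot(t, decomp.preprocessed, color="tab:green", lw=0.7,
                 label="waveform")
    axes[0].plot(t, decomp.amplitude, color="tab:red", lw=1.2,
                 label="amplitude")
    axes[0].set_ylabel("resp (a.u.)")
    axes[0].legend(loc="upper right")
    axes[1].plot(t, decomp.phase, color="k", lw=0.8)
    axes[1].set_ylabel("phase (rad)")
    axes[2].plot(t, decomp.frequency, color="tab:blue", lw=0.8)
    axes[2].set_ylabel("frequency (Hz)")
    axes[2].set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def measure_vs_indices(result, path: str | Path) -> None:
    """Each respiratory measure over time against the three HRV tracks."""
    d, tr = result.decomposition, result.track
    t = d.times
    measures = [("waveform", d.preprocessed), ("amplitude", d.amplitude),
                ("rate_inverted", d.rate_inverted)]
    fig, axes = plt.subplots(3, 1, figsize=(10, 8), sharex=True)
    for ax, (name, values) in zip(axes, measures):
        ax.plot(t, values, color=_MEASURE_COLORS[name], lw=0.7)
        ax.set_ylabel(name)
        ax2 = ax.twinx()
        ax2.plot(tr.grid_times, tr.hf_log, "k-", lw=0.6, alpha=0.7)
        ax2.plot(tr.grid_times, tr.rmssd_ms / np.nanmax(tr.rmssd_ms), "k--",
                 lw=0.6, alpha=0.7)
        ax2.plot(tr.grid_times, tr.cvi, "k:", lw=0.6, alpha=0.7)
        ax2.set_yticks([])
    axes[-1].set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def violin_z(cohort, path: str | Path) -> None:
    """Violin plot of Fisher-z correlations per measure and index."""
    fig, axes = plt.subplots(1, 3, figsize=(11, 4), sharey=True)
    for j, (ax, index_name) in enumerate(zip(axes, stats.INDICES)):
        data = []
        for i in range(3):
            z = np.array([s.z[i, j] for s in cohort.subjects])
            data.append(z[~np.isnan(z)])
        parts = ax.violinplot(data, showmeans=False, showextrema=False)
        for body, m in zip(parts["bodies"], stats.MEASURES):
            body.set_facecolor(_MEASURE_COLORS[m])
            body.set_alpha(0.5)
        for i, z in enumerate(data):
            ax.scatter(np.full(z.size, i + 1), z, s=8, color="gray", zorder=3)
            mean, se = z.mean(), z.std(ddof=1) / np.sqrt(z.size)
            ax.errorbar(i + 1, mean, yerr=se, fmt="_", color="k",
                        capsize=4, zorder=4)
        ax.set_title(index_name)
        ax.set_xticks([1, 2, 3], stats.MEASURES, rotation=20)
    axes[0].set_ylabel("Fisher z")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
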