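"""End-to-end orchestration: per-subject feature extraction, cohort
statistics, and file artifacts.

A run takes paired respiration/ECG channels (from disk or the simulator),
extracts the respiratory decomposition and the continuous HRV track,
correlates them within subject, and aggregates the Fisher-z matrices into
per-index repeated-measures ANOVAs with Bonferroni pairwise comparisons.
Every fixed analysis constant (HF band, R-R gate, window and grid lengths)
lives in ``RunConfig`` and is echoed to the run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import hrv, respiratory, simulate, stats
from .signals import SampledSignal

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Analysis constants; defaults are the standard protocol values."""

    fs: float = 500.0
    guard_s: float = 10.0
    window_s: float = 5.0
    grid_s: float = 0.1
    rr_bounds_ms: tuple[float, float] = (250.0, 1500.0)
    hf_band_hz: tuple[float, float] = (0.15, 0.40)
    alpha: float = 0.05
    min_pairs: int = 100
    hf_input: str = "beats"
    seed: int = 0

    def echo(self) -> None:
        """Log every constant, flagging overrides of the protocol defaults."""
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            default = f.default
            tag = "protocol default" if value == default else \
                f"override (default {default})"
            log.info("config %s = %r [%s]", f.name, value, tag)


@dataclass
class SubjectResult:
    subject_id: str
    decomposition: respiratory.RespDecomposition
    rr: hrv.RRSeries
    track: hrv.HRVTrack
    correlations: stats.SubjectCorrelations


@dataclass
class CohortStats:
    """Aggregated cohort outcome: per-index ANOVAs plus bookkeeping."""

    anovas: dict[str, stats.AnovaResult]
    subjects: list[stats.SubjectCorrelations]
    excluded: dict[str, str]


# ---------------------------------------------------------------------------
# signal file I/O: two-column CSV (time_s, value) + JSON sidecar with fs etc.

def write_signal_csv(signal: SampledSignal, path: str | Path,
                     sidecar: dict | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame({"time_s": signal.times, "value": signal.values})
    df.to_csv(path, index=False, float_format="%.9g")
    meta = {"fs": signal.fs, "t0": signal.t0, "name": signal.name}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_signal_csv(path: str | Path,
                    sidecar: str | Path | None = None) -> SampledSignal:
    """Load a two-column signal CSV with its JSON sidecar.

    The sidecar must provide ``fs``; the time column must be uniform at
    1/fs — a gap is rejected with its location.
    """
    path = Path(path)
    sc_path = Path(sidecar) if sidecar is not None else path.with_suffix(".json")
    if not sc_path.exists():
        raise ValueError(f"missing sidecar {sc_path} (fs is required)")
    meta = json.loads(sc_path.read_text())
    if "fs" not in meta:
        raise ValueError(f"sidecar {sc_path} has no 'fs' entry")
    fs = float(meta["fs"])
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path} is not a two-column CSV")
    t = df.iloc[:, 0].to_numpy(float)
    v = df.iloc[:, 1].to_numpy(float)
    bad = ~np.isfinite(v)
    if bad.any():
        raise ValueError(f"{path}: {bad.sum()} NaN/inf samples "
                         f"(first at row {int(np.flatnonzero(bad)[0])})")
    dt = np.diff(t)
    tol = 0.01 / fs
    irregular = np.abs(dt - 1.0 / fs) > tol
    if irregular.any():
        k = int(np.flatnonzero(irregular)[0])
        raise ValueError(f"{path}: non-uniform time step at row {k} "
                         f"(t={t[k]:.6g} -> {t[k + 1]:.6g}, expected step "
                         f"{1.0 / fs:.6g})")
    return SampledSignal(values=v, fs=fs, t0=float(t[0]),
                         name=str(meta.get("name", "")))


# ---------------------------------------------------------------------------

def analyze_subject(resp: SampledSignal, ecg: SampledSignal,
                    config: RunConfig, subject_id: str = "S00"
                    ) -> SubjectResult:
    """Run the full per-subject pipeline in memory."""
    if abs(resp.duration - ecg.duration) > 1.0:
        raise ValueError(
            f"{subject_id}: respiration ({resp.duration:.1f} s) and ECG "
            f"({ecg.duration:.1f} s) durations differ by more than 1 s")
    decomp = respiratory.decompose_respiration(resp, guard_s=config.guard_s)
    peaks = hrv.detect_r_peaks(ecg)
    rr = hrv.clean_and_interpolate_rr(peaks, bounds_ms=config.rr_bounds_ms)
    track = hrv.sliding_hrv(rr, window_s=config.window_s, grid_s=config.grid_s,
                            band_hz=config.hf_band_hz, hf_input=config.hf_input)
    corr = stats.subject_correlations(decomp, track, subject_id=subject_id,
                                      guard_s=config.guard_s,
                                      min_pairs=config.min_pairs)
    return SubjectResult(subject_id=subject_id, decomposition=decomp, rr=rr,
                         track=track, correlations=corr)


def run_subject(resp_file: str | Path, ecg_file: str | Path,
                config: RunConfig, out_dir: str | Path,
                subject_id: str = "S00") -> SubjectResult:
    """File-based per-subject run: reads channels, writes all tables."""
    resp = read_signal_csv(resp_file)
    ecg = read_signal_csv(ecg_file)
    result = analyze_subject(resp, ecg, config, subject_id=subject_id)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_subject_tables(result, out)
    return result


def write_subject_tables(result: SubjectResult, out: Path) -> None:
    d = result.decomposition
    pd.DataFrame({
        "time_s": d.times, "preprocessed": d.preprocessed,
        "amplitude": d.amplitude, "phase": d.phase,
        "frequency": d.frequency, "rate_inverted": d.rate_inverted,
    }).to_csv(out / f"{result.subject_id}_decomposition.csv", index=False,
              float_format="%.9g")
    rr = result.rr
    pd.DataFrame({
        "beat_time_s": rr.beat_times[1:], "rr_ms": rr.rr_ms,
        "valid": rr.valid.astype(int), "rr_repaired_ms": rr.rr_repaired_ms,
    }).to_csv(out / f"{result.subject_id}_rr.csv", index=False,
              float_format="%.9g")
    tr = result.track
    pd.DataFrame({
        "time_s": tr.grid_times, "hf_log": tr.hf_log,
        "rmssd_ms": tr.rmssd_ms, "cvi": tr.cvi,
        "n_beats": tr.n_beats_per_window,
    }).to_csv(out / f"{result.subject_id}_hrv.csv", index=False,
              float_format="%.9g")
    correlation_table([result.correlations]).to_csv(
        out / f"{result.subject_id}_correlations.csv", index=False,
        float_format="%.9g")


def correlation_table(subjects: list[stats.SubjectCorrelations]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        for i, m in enumerate(stats.MEASURES):
            for j, ix in enumerate(stats.INDICES):
                rows.append({"subject": s.subject_id, "measure": m,
                             "index": ix, "rho": s.rho[i, j],
                             "z": s.z[i, j],
                             "n_pairs": int(s.n_pairs[i, j])})
    return pd.DataFrame(rows)


def cohort_from_subjects(results: list[SubjectResult | None],
                         ids: list[str],
                         errors: dict[str, str],
                         config: RunConfig) -> CohortStats:
    usable = [r.correlations for r in results if r is not None]
    if len(usable) < 3:
        detail = "; ".join(f"{k}: {v}" for k, v in errors.items()) or "none"
        raise ValueError(f"fewer than 3 usable subjects (failures: {detail})")
    anovas = stats.cohort_anovas(usable)
    return CohortStats(anovas=anovas, subjects=usable, excluded=errors)


def run_cohort_signals(channel_pairs: list[tuple[SampledSignal, SampledSignal]],
                       config: RunConfig,
                       ids: list[str] | None = None
                       ) -> tuple[CohortStats, list[SubjectResult]]:
    """In-memory cohort run with per-subject crash isolation."""
    if ids is None:
        ids = [f"S{i:02d}" for i in range(len(channel_pairs))]
    results: list[SubjectResult | None] = []
    errors: dict[str, str] = {}
    for sid, (resp, ecg) in zip(ids, channel_pairs):
        try:
            results.append(analyze_subject(resp, ecg, config, subject_id=sid))
        except Exception as exc:  # noqa: BLE001 - isolate per-subject failures
            log.warning("subject %s excluded: %s", sid, exc)
            errors[sid] = str(exc)
            results.append(None)
    cohort = cohort_from_subjects(results, ids, errors, config)
    return cohort, [r for r in results if r is not None]


def anova_summary(cohort: CohortStats) -> dict:
    """JSON-serializable cohort summary."""
    out: dict = {"excluded": cohort.excluded, "indices": {}}
    for name, res in cohort.anovas.items():
        out["indices"][name] = {
            "n_subjects": res.n_subjects,
            "F": res.F, "df": list(res.df), "p": res.p,
            "partial_eta_sq": res.partial_eta_sq,
            "pairwise": [{
                "pair": list(p.pair), "mean_difference": p.mean_difference,
                "se": p.se, "t": p.t, "df": p.df, "p_raw": p.p_raw,
                "p_bonferroni": p.p_bonferroni,
            } for p in res.pairwise],
        }
    z_means = {}
    for j, ix in enumerate(stats.INDICES):
        z = np.array([s.z[:, j] for s in cohort.subjects])
        z_means[ix] = {m: float(np.nanmean(z[:, i]))
                       for i, m in enumerate(stats.MEASURES)}
    out["mean_z"] = z_means
    return out


def run_cohort(subject_files: list[tuple[str | Path, str | Path]],
               config: RunConfig, out_dir: str | Path,
               make_figures: bool = True) -> CohortStats:
    """File-based cohort run: writes tables, JSON summary, and figures."""
    config.echo()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pairs, ids = [], []
    errors: dict[str, str] = {}
    for i, (rf, ef) in enumerate(subject_files):
        sid = f"S{i:02d}"
        ids.append(sid)
        try:
            pairs.append((read_signal_csv(rf), read_signal_csv(ef)))
        except Exception as exc:  # noqa: BLE001
            errors[sid] = str(exc)
            pairs.append(None)

    results: list[SubjectResult | None] = []
    for sid, pair in zip(ids, pairs):
        if pair is None:
            results.append(None)
            continue
        try:
            res = analyze_subject(pair[0], pair[1], config, subject_id=sid)
            write_subject_tables(res, out)
            results.append(res)
        except Exception as exc:  # noqa: BLE001
            log.warning("subject %s excluded: %s", sid, exc)
            errors[sid] = str(exc)
            results.append(None)

    cohort = cohort_from_subjects(results, ids, errors, config)
    correlation_table(cohort.subjects).to_csv(out / "correlations.csv",
                                              index=False, float_format="%.9g")
    write_report(cohort, out)
    if make_figures:
        from . import plots
        plots.violin_z(cohort, out / "fig_cohort_z.png")
        exemplar = next(r for r in results if r is not None)
        plots.decomposition_traces(exemplar.decomposition,
                                   out / "fig_decomposition.png")
        plots.measure_vs_indices(exemplar, out / "fig_measures_vs_hrv.png")
    return cohort


def write_report(cohort: CohortStats, out: Path) -> None:
    summary = anova_summary(cohort)
    (out / "cohort_summary.json").write_text(json.dumps(summary, indent=1,
                                                        sort_keys=True))
    rows = []
    for name, res in cohort.anovas.items():
        rows.append({"index": name, "n": res.n_subjects, "F": res.F,
                     "df1": res.df[0], "df2": res.df[1], "p": res.p,
                     "partial_eta_sq": res.partial_eta_sq})
    pd.DataFrame(rows).to_csv(out / "anova.csv", index=False,
                              float_format="%.9g")
    rows = []
    for name, res in cohort.anovas.items():
        for p in res.pairwise:
            rows.append({"index": name, "measure_a": p.pair[0],
                         "measure_b": p.pair[1],
                         "mean_difference": p.mean_difference, "se": p.se,
                         "t": p.t, "df": p.df, "p_raw": p.p_raw,
                         "p_bonferroni": p.p_bonferroni})
    pd.DataFrame(rows).to_csv(out / "pairwise.csv", index=False,
                              float_format="%.9g")


def simulate_to_dir(n_subjects: int, scenario: str, out_dir: str | Path,
                    config_template: simulate.SimConfig | None = None,
                    master_seed: int = 0) -> list[tuple[Path, Path]]:
    """Simulate a cohort and write per-subject CSV channels + sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = simulate.simulate_cohort(n_subjects, config_template, scenario,
                                        master_seed=master_seed)
    files = []
    for s in subjects:
        meta = {"seed": s.config.seed, "scenario": scenario,
                "subject": s.subject_id}
        rf = out / f"{s.subject_id}_resp.csv"
        ef = out / f"{s.subject_id}_ecg.csv"
        write_signal_csv(s.resp, rf, sidecar=meta)
        write_signal_csv(s.ecg, ef, sidecar=meta)
        files.append((rf, ef))
    return files
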