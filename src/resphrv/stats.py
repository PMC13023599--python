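"""Within-participant correlations and the group-level comparison.

Each participant contributes a 3x3 matrix of Spearman correlations between
respiratory measures (preprocessed waveform, instantaneous amplitude,
sign-inverted instantaneous rate) and vagal HRV indices (log HF, RMSSD,
CVI). Correlations are Fisher z-transformed and, per index, the three
respiratory measures are compared with a one-way repeated-measures ANOVA
(partial eta squared as effect size) followed by Bonferroni-corrected paired
t-tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .hrv import HRVTrack
from .respiratory import RespDecomposition

log = logging.getLogger(__name__)

MEASURES = ("waveform", "amplitude", "rate_inverted")
INDICES = ("hf_log", "rmssd_ms", "cvi")
MIN_PAIRS = 100


@dataclass
class SubjectCorrelations:
    """Per-subject correlation matrices (measures x indices)."""

    subject_id: str
    rho: np.ndarray          # 3x3 Spearman rho
    z: np.ndarray            # 3x3 Fisher z
    n_pairs: np.ndarray      # 3x3 pair counts


@dataclass
class PairwiseComparison:
    pair: tuple[str, str]
    mean_difference: float
    se: float
    t: float
    df: int
    p_raw: float
    p_bonferroni: float


@dataclass
class AnovaResult:
    """One-way within-subject ANOVA over the three respiratory measures."""

    index_name: str
    n_subjects: int
    F: float
    df: tuple[int, int]
    p: float
    partial_eta_sq: float
    pairwise: list[PairwiseComparison] = field(default_factory=list)


def align_pairs(measure_values: np.ndarray, measure_fs: float,
                track: HRVTrack, guard_s: float,
                record_duration_s: float | None = None
                ) -> tuple[np.ndarray, np.ndarray, int]:
    """Pair a respiratory measure with an HRV track on the track's grid.

    The measure (sampled at ``measure_fs``) is decimated to the 0.1 s HRV
    grid by nearest-sample lookup (exact when the grid times are sample
    times, as they are for integer-ratio rates). Grid points inside the
    guard bands or with any missing HRV value are dropped pairwise.

    Returns the measure array, the matching (n, 3) HRV matrix in
    ``INDICES`` column order, and the pair count.
    """
    n = measure_values.size
    dur = record_duration_s if record_duration_s is not None else (n - 1) / measure_fs
    idx = np.round(track.grid_times * measure_fs).astype(int)
    ok = (idx >= 0) & (idx < n)
    ok &= (track.grid_times >= guard_s) & (track.grid_times <= dur - guard_s)
    hrv_cols = np.column_stack([track.hf_log, track.rmssd_ms, track.cvi])
    ok &= ~np.isnan(hrv_cols).any(axis=1)
    x = measure_values[idx[ok]]
    return x, hrv_cols[ok], int(ok.sum())


def spearman_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-aware Spearman correlation (Pearson on average ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("inputs must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("constant input: Spearman correlation undefined")
        return np.nan
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    n = x.size
    if np.unique(x).size == n and np.unique(y).size == n:
        # tie-free: the exact rank-difference formula (integer arithmetic,
        # so monotone data gives exactly +/-1)
        d = rx - ry
        return float(1.0 - 6.0 * (d * d).sum() / (n * (n * n - 1.0)))
    rho = scipy.stats.spearmanr(x, y).statistic
    return float(rho)


def fisher_z(rho: float | np.ndarray) -> float | np.ndarray:
    """Variance-stabilizing atanh transform, clipping |rho| at 1 - 1e-7."""
    rho = np.asarray(rho, dtype=float)
    clipped = np.clip(rho, -1 + 1e-7, 1 - 1e-7)
    if np.any(np.abs(rho) >= 1):
        log.warning("|rho| = 1 clipped before Fisher z transform")
    z = np.arctanh(clipped)
    return float(z) if z.ndim == 0 else z


def subject_correlations(decomp: RespDecomposition, track: HRVTrack,
                         subject_id: str = "S00",
                         guard_s: float | None = None,
                         min_pairs: int = MIN_PAIRS) -> SubjectCorrelations:
    """Spearman/Fisher-z matrix for one subject.

    Cells with fewer than ``min_pairs`` aligned points, or an undefined
    correlation, are NaN and logged.
    """
    guard = decomp.guard_s if guard_s is None else guard_s
    dur = (decomp.preprocessed.size - 1) / decomp.fs
    measure_arrays = {
        "waveform": decomp.preprocessed,
        "amplitude": decomp.amplitude,
        "rate_inverted": decomp.rate_inverted,
    }
    rho = np.full((3, 3), np.nan)
    npairs = np.zeros((3, 3), dtype=int)
    xs = []
    y_mat = None
    for mname in MEASURES:
        x, y_mat, n_ok = align_pairs(measure_arrays[mname], decomp.fs, track,
                                     guard, dur)
        xs.append(x)
    npairs[:] = n_ok
    if n_ok < min_pairs:
        log.warning("%s: only %d aligned pairs (< %d); all cells flagged "
                    "missing", subject_id, n_ok, min_pairs)
    else:
        # Spearman = Pearson on average ranks; rank each series once and
        # correlate jointly (equivalent to spearman_corr per cell)
        ranked = np.vstack([scipy.stats.rankdata(v) for v in xs + list(y_mat.T)])
        sds = ranked.std(axis=1)
        corr = np.corrcoef(ranked) if np.all(sds > 0) else None
        for i, mname in enumerate(MEASURES):
            for j, iname in enumerate(INDICES):
                if corr is None and (sds[i] == 0 or sds[3 + j] == 0):
                    log.warning("%s: constant input for %s vs %s; cell "
                                "flagged missing", subject_id, mname, iname)
                    continue
                if corr is not None:
                    rho[i, j] = corr[i, 3 + j]
                else:
                    rho[i, j] = spearman_corr(xs[i], y_mat[:, j])
    z = np.where(np.isnan(rho), np.nan, fisher_z(np.nan_to_num(rho)))
    return SubjectCorrelations(subject_id=subject_id, rho=rho, z=z,
                               n_pairs=npairs)


def _greenhouse_geisser_eps(data: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity correction factor for one within factor."""
    cov = np.cov(data, rowvar=False, ddof=1)
    k = cov.shape[0]
    mean_diag = np.trace(cov) / k
    num = (k * (mean_diag - cov.mean())) ** 2
    den = (k - 1) * (np.sum(cov * cov) - 2 * k * np.sum(cov.mean(axis=1) ** 2)
                     + k * k * cov.mean() ** 2)
    eps = num / den if den > 0 else 1.0
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova(z_matrix: np.ndarray, index_name: str = "",
             sphericity_correction: bool = False) -> AnovaResult:
    """One-way repeated-measures ANOVA on an (subjects x measures) matrix.

    Subjects with any missing cell are dropped listwise. Degrees of freedom
    are the uncorrected (k-1, (k-1)(n-1)); the Greenhouse-Geisser correction
    is available as an option.
    """
    z = np.asarray(z_matrix, dtype=float)
    complete = ~np.isnan(z).any(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        log.warning("%s: dropping %d subjects with missing cells", index_name,
                    dropped)
    z = z[complete]
    n, k = z.shape
    if n < 3:
        raise ValueError("repeated-measures ANOVA needs >= 3 complete subjects")

    grand = z.mean()
    ss_total = float(((z - grand) ** 2).sum())
    ss_subject = float(k * ((z.mean(axis=1) - grand) ** 2).sum())
    ss_measure = float(n * ((z.mean(axis=0) - grand) ** 2).sum())
    ss_error = ss_total - ss_subject - ss_measure
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_measure = ss_measure / df1
    ms_error = ss_error / df2
    tol = 1e-12 * max(ss_total, 1e-300)
    if ss_error <= tol:
        f_stat = np.inf if ss_measure > tol else 0.0
        p = 0.0 if ss_measure > tol else 1.0
        log.warning("%s: zero error variance in RM-ANOVA", index_name)
    else:
        f_stat = ms_measure / ms_error
        eps = _greenhouse_geisser_eps(z) if sphericity_correction else 1.0
        p = float(scipy.stats.f.sf(f_stat, eps * df1, eps * df2))
    pes = ss_measure / (ss_measure + ss_error) if (ss_measure + ss_error) > 0 else 0.0
    return AnovaResult(index_name=index_name, n_subjects=n, F=float(f_stat),
                       df=(df1, df2), p=p, partial_eta_sq=float(pes),
                       pairwise=bonferroni_pairwise(z))


def bonferroni_pairwise(z_matrix: np.ndarray,
                        names: tuple[str, ...] = MEASURES
                        ) -> list[PairwiseComparison]:
    """Paired t-tests for the three measure pairs, Bonferroni-corrected (x3).

    The sign convention is first-listed measure minus second.
    """
    z = np.asarray(z_matrix, dtype=float)
    z = z[~np.isnan(z).any(axis=1)]
    n = z.shape[0]
    if n < 3:
        raise ValueError("paired comparisons need >= 3 complete subjects")
    pairs = [(0, 1), (0, 2), (1, 2)]
    out = []
    for i, j in pairs:
        d = z[:, i] - z[:, j]
        mean = float(d.mean())
        sd = float(d.std(ddof=1))
        se = sd / np.sqrt(n)
        if se == 0:
            t_stat = np.inf if mean != 0 else 0.0
            p_raw = 0.0 if mean != 0 else 1.0
            log.warning("zero-variance paired differences for %s vs %s",
                        names[i], names[j])
        else:
            t_stat = mean / se
            p_raw = float(2 * scipy.stats.t.sf(abs(t_stat), n - 1))
        out.append(PairwiseComparison(
            pair=(names[i], names[j]), mean_difference=mean, se=float(se),
            t=float(t_stat), df=n - 1, p_raw=p_raw,
            p_bonferroni=min(1.0, 3.0 * p_raw)))
    return out


def cohort_anovas(subjects: list[SubjectCorrelations],
                  sphericity_correction: bool = False) -> dict[str, AnovaResult]:
    """RM-ANOVA (with pairwise comparisons) for each PSNS index."""
    out = {}
    for j, index_name in enumerate(INDICES):
        z = np.array([s.z[:, j] for s in subjects])
        out[index_name] = rm_anova(z, index_name=index_name,
                                   sphericity_correction=sphericity_correction)
    return out


def validate_window_choice(rr_list: list, windows: list[float],
                           grid_s: float = 0.1) -> dict[float, dict[str, float]]:
    """Correlate time-averaged windowed indices with whole-record indices.

    For each candidate window length, every subject's windowed track is
    averaged over time and correlated (Pearson, across subjects) with the
    index computed once over the whole recording. Reproduces the
    window-length justification analysis on a synthetic cohort.
    """
    from .hrv import sliding_hrv, whole_record_indices

    if len(rr_list) < 3:
        raise ValueError("need at least 3 subjects")
    whole = {name: [] for name in INDICES}
    for rr in rr_list:
        w = whole_record_indices(rr)
        for name in INDICES:
            whole[name].append(w[name])

    out: dict[float, dict[str, float]] = {}
    for win in windows:
        means = {name: [] for name in INDICES}
        for rr in rr_list:
            span = rr.beat_times[-1] - rr.beat_times[0]
            if win >= span / 2:
                idx = whole_record_indices(rr)
                for name in INDICES:
                    means[name].append(idx[name])
                continue
            track = sliding_hrv(rr, window_s=win, grid_s=grid_s)
            for name, arr in (("hf_log", track.hf_log),
                              ("rmssd_ms", track.rmssd_ms),
                              ("cvi", track.cvi)):
                means[name].append(float(np.nanmean(arr)))
        out[win] = {
            name: float(np.corrcoef(means[name], whole[name])[0, 1])
            for name in INDICES
        }
    return out
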