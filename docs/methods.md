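# Methods

This note documents the models, numerical choices, and validation design
behind `resphrv`, in the order the data flow through the pipeline.

## Respiratory preprocessing

The belt signal is reduced to a quasi-monocomponent waveform in three
steps: removal of baseline drift below 0.01 Hz, a 2 Hz low-pass against
measurement noise, and a final 0.75 Hz low-pass that leaves the dominant
respiratory rhythm (spontaneous breathing sits near 0.2–0.3 Hz). The two
low-passes are 4th-order Butterworth filters applied forward–backward
(zero phase, even-reflection padding), standard practice for physiological
band-limiting because it preserves event timing.

The drift removal deserves explanation. A recursive high-pass at 0.01 Hz
has transient modes with ~40 s time constants; on a 5-minute record its
edge transients contaminate far more than the 10 s guard bands we are
willing to discard (we measured 2–5% envelope error at 10 s from the
edges, regardless of padding strategy). We therefore estimate the drift as
an explicit trend and subtract it: the signal is averaged in blocks of one
dominant breath period (so respiratory-band content largely cancels in the
block means), the block series is extended by point reflection about
robust endpoint levels (local linear fits), and a penalized smoothing
spline is fitted whose curvature penalty places the half-power point at
0.01 Hz with a 4th-order rolloff — the same asymptotic behaviour as the
Butterworth, without its edge transients. On a pure 0.25 Hz tone the whole
chain is amplitude-accurate to ±0.6% outside 10 s guard bands, removes a
DC offset exactly, attenuates a 5 Hz contaminant by >60 dB, and is
idempotent to 0.015%.

Degenerate inputs: records shorter than 30 s are rejected (the drift
estimate would be meaningless); an all-zero signal yields zero amplitude
and zero phase by convention.

## Hilbert decomposition

The analytic signal is built by frequency-domain construction on the full
record (`scipy.signal.hilbert`). Its modulus is the instantaneous
amplitude (respiratory depth); its unwrapped argument is the instantaneous
phase. Because noise can still produce transient phase reversals, the
phase is corrected: every decreasing run is bridged by linear
interpolation between its bracketing extrema (the sample where the phase
stopped increasing and the first sample that recovers to that level), and
the phase increments are then low-passed at 0.75 Hz and re-integrated —
filtering increments rather than absolute phase avoids re-introducing
drift into the phase slope. This repair-and-smooth step is iterated up to
ten times; an iteration that finds no decreasing run is a no-op, so the
procedure stops at a fixpoint and monotone input passes through unchanged.
A final bridging pass guarantees forward differences ≥ −1e−6 rad on any
input.

Instantaneous frequency is the central-difference derivative of the
corrected phase over 2π (one-sided at the endpoints, exact for linear
phase). Its sign is inverted for the correlation analysis so that — like
depth — larger values are expected to associate positively with vagal
indices (slower breathing = larger value). The decomposition carries a
configurable guard band (default 10 s) that downstream correlation stages
exclude.

On AM/FM test signals in the spontaneous-breathing range (carriers
0.15–0.35 Hz, modulation ≤ 0.05 Hz), interior envelope and frequency RMSE
are both well under 5% of the mean envelope / carrier.

## R peaks and R–R cleaning

QRS detection is the classic Pan–Tompkins cascade: 5–15 Hz band-pass,
five-point derivative, squaring, 150 ms moving-window integration,
adaptive signal/noise thresholds on both the integrated and band-passed
signals (initialized from the first 2 s), a 200 ms refractory period, a
T-wave discrimination rule inside 360 ms, and search-back at 1.66× the
running R–R average when a beat is overdue. Reported peak times are
refined to the local maximum of the band-passed signal within ±100 ms. On
noise-free template ECG detection is a bijection with the true beats at
sample accuracy; at 20 dB SNR sensitivity and positive predictivity stay
above 99%.

R–R intervals outside 250–1500 ms (inclusive bounds) are flagged invalid
and replaced by a natural cubic spline over beat index fitted to the valid
intervals only; invalid runs at the record edges are held at the nearest
valid value. At least four valid intervals are required.

## Continuous vagal indices

Indices are computed from the beats inside a centred 5 s window for every
0.1 s grid time spanning the beat support (windows that extend past the
first/last beat are missing). Each interval is timestamped at its ending
beat. Minimum beats per window: 3 for RMSSD, 4 for HF and CVI; below the
minimum the value is missing, never zero.

- **RMSSD**: root mean square of successive interval differences (ms).
- **CVI**: log10(SD1·SD2) with population standard deviations of the
  rotated Poincaré coordinates (rr_{k+1} ∓ rr_k)/√2. A floor of
  ε = 1e−6 ms² keeps degenerate windows finite: CVI ≥ log10(ε).
- **HF power**: Lomb–Scargle periodogram of the mean-subtracted intervals
  at their (irregular) beat times — the estimator exists precisely to
  avoid resampling — evaluated on a fixed 0.15–0.40 Hz grid (0.01 Hz
  step), scaled to a one-sided density and trapezoid-integrated to ms²,
  reported as log10(power + ε). On a 60 s window a sinusoidal modulation
  of amplitude *a* recovers the theoretical power a²/2 within a few
  percent (the remainder is sidelobe leakage outside the band). A
  documented switch (`hf_input="resampled"`) computes HF from the
  PCHIP-resampled uniform series instead.

A 5 s window holds only ~6 beats — less than one full cycle of a 0.15 Hz
component — so HF values at this window length are high-variance,
order-of-magnitude indicators; the validation suite asserts exact spectral
properties only at 60 s windows and ordinal properties at 5 s. The
`validate_window_choice` helper reproduces the window-length justification
(correlating time-averaged windowed indices with whole-record indices
across a cohort).

For alignment and plotting, the repaired tachogram is also resampled to
the 0.1 s grid with a shape-preserving piecewise cubic Hermite polynomial
(PCHIP; monotone, no overshoot).

Consecutive grid times usually share the same beat subset, so windowed
indices are computed once per unique beat subset; the sliding HF values
are evaluated for all windows at once by a vectorized implementation of
the same classical Lomb–Scargle expression (the per-window scipy path is
retained and the two are asserted equal in the tests).

## Within-participant correlation and group comparison

Each respiratory measure (preprocessed waveform, amplitude, sign-inverted
rate) is decimated to the HRV grid by nearest-sample lookup; grid points
inside the guard bands or with any missing index are dropped pairwise, and
cells with fewer than 100 pairs are flagged missing. Spearman correlations
are computed tie-aware (Pearson on average ranks; the exact rank-difference
formula when there are no ties), then Fisher z-transformed
(`z = atanh(ρ)`, clipping |ρ| at 1 − 1e−7).

Per index, the three measures are compared with a one-way within-subject
ANOVA: F = MS_measure/MS_error with df = (k−1, (k−1)(n−1)) and partial
η² = SS_measure/(SS_measure + SS_error). Subjects with any missing cell
are dropped listwise (the within-subject decomposition needs balanced
data). No sphericity correction is applied by default — the uncorrected
df are the conventional report for this design — but a Greenhouse–Geisser
option is available (its ε matches `pingouin` to machine precision).
Pairwise comparisons are paired t-tests on the z differences (first-listed
measure minus second), Bonferroni-corrected by the factor 3 and capped at
1. Correlations are zero-lag; lead/lag structure between respiration and
HRV is out of scope.

## Synthetic cohort generator

Respiration is `depth(t)·cos(φ(t)) + drift + noise` with
`dφ/dt = 2π·rate(t)`. Depth and rate envelopes are Gaussian processes
low-passed at 0.05 Hz and z-scored over the record (only slow variation
matters to the analysis), scaled by `depth_sd` / `breath_rate_sd_hz`
around their base values; depth is floored at 10% of `base_depth` to
avoid amplitude sign degeneracy, and Poisson-timed sighs add transient
Gaussian envelope boosts (one per ~2 min by default). The drift term is a
0.004 Hz sinusoid exercising the drift-removal stage.

Beats come from an IPFM model: a beat is emitted whenever
∫(1 + m(t))·HR₀/60 dt crosses an integer. The vagal modulation is

    m(t) = clip(rsa_base + g_d·z(depth) + g_r·z(rate), 0, 0.75)·sin(φ_resp)
           + intrinsic(t)

so RSA is phase-locked within the breath (heart rate rises during
inspiration) and its amplitude tracks depth and/or rate with gains
`g_d`/`g_r`. Two terms beyond the bare coupling are deliberate: a baseline
RSA amplitude (`rsa_base`, default 0.1 — RSA exists even when coupling is
absent), and a respiration-independent band-limited modulation
(`intrinsic_hrv_sd`, default 0.05, low-passed at 0.5 Hz) standing in for
non-respiratory autonomic variability. Without the intrinsic term a
zero-coupling simulation would produce an exactly constant R–R series,
degenerate HRV tracks, and undefined correlations — no Type-I error study
would be possible. The amplitude bracket is clipped at zero (a z-scored
envelope would otherwise flip the RSA phase for below-average depths and
break the depth→RMSSD monotonicity) and saturates at 0.75 so sigh-driven
excursions stay physiological; a modulation reaching |m| ≥ 1 is rejected.

ECG morphology is a fixed template train (Gaussian R wave of ~20 ms width
and unit amplitude, small P and T bumps) plus white noise — sufficient for
a detector whose robustness is tested via added noise, with no claim to
pathological morphologies.

Cohorts derive per-subject seeds from a master seed via a counter-based
`SeedSequence` scheme (subject *i* is reproducible in isolation) and
jitter mean heart rate (±7 bpm), base breath rate (±0.03 Hz), base depth
and intrinsic modulation (lognormal, ~20–30%) across subjects. The named
scenarios set the gains: `depth-coupled` (g, 0), `rate-coupled` (0, g),
`null` (0, 0, with `rsa_base` also zeroed so cardiac variability is
independent of respiration by construction). The shipped default gain is
g = 0.2, chosen so the depth-coupled scenario reproduces the qualitative
target pattern (amplitude ≫ rate in correlation strength) without
saturating |m|; no quantitative coupling strength is claimed.

What the generator does **not** emulate: motion artifacts and electrode
noise beyond white noise, ectopic beats, sympathetic/LF dynamics, Mayer
waves with a distinct spectral peak, respiratory mechanics, or realistic
multi-lead ECG morphology. Passing tests therefore demonstrate that the
pipeline recovers the modelled structure, not that it is robust to every
failure mode of real recordings.

## Validation design and problem sizes

The validation studies (`resphrv.studies`, exercised by the test suite and
`scripts/acceptance.py`) use these sizes, chosen to make each check
informative at interactive runtimes:

- decomposition recovery and detector fidelity: single 300 s records at
  500 Hz;
- headline ordering: one 33-subject depth-coupled cohort, 300 s records
  at 500 Hz;
- Type-I calibration: 400 independent 33-subject null cohorts with 60 s
  records at 100 Hz (the detector needs ≥100 Hz; shorter records and the
  lower rate keep 13,200 subject pipelines tractable while leaving ~350
  correlation pairs per subject);
- window validation: one 33-subject cohort at 250 Hz.

The Type-I study measures the rejection rate of the uncorrected RM-ANOVA
under the null scenario. The three measures have unequal correlation
variances (the fast-oscillating waveform decorrelates quickly against the
slow HRV tracks, so its ρ is tightly concentrated; the slow amplitude and
rate envelopes give much wider ρ distributions), a mild sphericity
violation that biases the uncorrected test slightly liberal — measured at
~6–7% against the nominal 5%.

## Known limitations

- The 0.01 Hz drift removal attenuates but does not annihilate drift close
  to the corner (≈29% of a 0.008 Hz component survives) — inherent to any
  4th-order response at this corner.
- HF at 5 s windows is a high-variance ordinal indicator (see above).
- The Spearman correlations use every 0.1 s grid point; the series are
  strongly autocorrelated, so per-subject ρ magnitudes should not be read
  as if computed from independent samples. The group-level comparison is
  unaffected (it operates on per-subject summaries).
- Guard bands (default 10 s) are excluded from correlations but the HRV
  track near the record edges still rests on fewer windows.
- The generator's coupling is instantaneous and noise-free in phase;
  real RSA has lags and breath-by-breath irregularity the model omits.
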