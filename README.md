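# resphrv

Which representation of spontaneous breathing best tracks parasympathetic
cardiac activity: the raw respiratory waveform, respiratory **depth**, or
respiratory **rate**?

`resphrv` is a Python package for answering that question from paired
respiratory-belt and ECG recordings. It decomposes the continuous belt
signal with the Hilbert transform — the analytic signal
`s_a(t) = s(t) + jH[s](t) = s_m(t) e^{jφ(t)}` yields the instantaneous
amplitude `s_m(t)` (depth) and the instantaneous frequency
`s_f(t) = (1/2π) dφ/dt` (rate) — extracts continuous vagal heart-rate-
variability indices from the ECG (log HF power 0.15–0.40 Hz via
Lomb–Scargle, RMSSD, and the Poincaré cardiac vagal index
`CVI = log10(SD1·SD2)`) on a 5 s sliding window at 0.1 s resolution, and
compares the three respiratory measures by within-participant Spearman
correlation, Fisher z transform, and one-way repeated-measures ANOVA with
Bonferroni-corrected paired comparisons.

Because paired cardiorespiratory recordings with known ground truth are
hard to come by, the package ships a synthetic cohort generator: an AM/FM
respiration model with slowly drifting depth and rate (plus occasional
sighs), and an integral-pulse-frequency-modulation (IPFM) beat generator
whose respiratory sinus arrhythmia amplitude can be coupled, with a
configurable gain, to depth and/or rate. Every stage of the analysis is
validated against this ground truth.

Intended users: researchers in autonomic/cardiorespiratory physiology and
biomedical signal processing who want a tested, scriptable implementation
of this analysis — or a controllable simulator to probe its statistical
behaviour.

## Worked example

Simulate a depth-coupled participant and run the full per-subject pipeline:

```python
import numpy as np
import resphrv as rp

cfg = rp.SimConfig(duration_s=300.0, fs=500.0, rsa_gain_depth=0.2, seed=3)
subject = rp.simulate_subject(cfg)

result = rp.analyze_subject(subject.resp, subject.ecg, rp.RunConfig())
print(np.round(result.correlations.rho, 3))
```

Output:

```
[[-0.013 -0.014 -0.006]
 [ 0.862  0.858  0.864]
 [-0.015 -0.034 -0.012]]
```

Rows are the respiratory measures (waveform, instantaneous amplitude,
sign-inverted instantaneous rate); columns the vagal indices (log HF,
RMSSD, CVI). In this simulation the RSA amplitude was coupled to
respiratory depth, and the analysis recovers exactly that structure: the
instantaneous amplitude correlates strongly with all three vagal indices
(ρ ≈ 0.86), while the rate measure and the raw oscillating waveform do
not — the waveform's fast polarity changes average out against the slow
HRV tracks.

The same can be driven from the shell:

```bash
resphrv simulate --scenario depth-coupled --n 33 --duration 300 --seed 7 --out signals/
resphrv report --in signals/ --out report/
# or in one step:
resphrv run-all --scenario depth-coupled --n 33 --seed 7 --out study/
```

`report/` then contains per-subject decomposition/RR/HRV tables, the
cohort correlation table, the per-index ANOVA and pairwise tables, a JSON
summary, and violin/trace figures.

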