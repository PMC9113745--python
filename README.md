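# sleepmicro

Analysis of NREM-sleep EEG microarchitecture: detection of sleep spindles
and slow oscillations, their temporal and phase coupling, intra-spindle
frequency dynamics, spectral and directed (phase-slope-index) connectivity,
and covariate-adjusted case/control statistics with permutation-based
multiple-testing control and SVD-component-based prediction.

The package is aimed at sleep/psychiatry researchers who quantify
thalamocortical function from overnight polysomnography — for example in
case/control studies of schizophrenia, where reduced spindle density,
altered spindle chirp, and shifted SO–spindle coupling are candidate
biomarkers. Because raw clinical recordings are rarely shareable, the
package ships a synthetic-data generator that produces N2-like multichannel
EEG with known ground-truth events and simulated case/control cohorts, so
every stage of the pipeline is testable end to end.

## What it computes

**Spindles** (slow ~11 Hz and fast ~15 Hz) are detected from the smoothed
magnitude of a complex Morlet wavelet transform: events must exceed 4.5×
the channel's mean coefficient for ≥ 0.3 s inside an interval ≥ 0.5 s above
2× the mean; intervals > 3 s are rejected and neighbors within 0.5 s merged
(unless the merge exceeds 3 s). Per event the pipeline reports amplitude,
duration, integrated spindle activity (ISA), observed frequency, and chirp
— the implied-frequency difference between the second and first event half
from zero-crossing intervals.

**Slow oscillations** are zero-crossing-delimited biphasic waves (negative
half-wave 0.3–1.5 s, positive peak within 1 s of the up-crossing) filtered
either by absolute amplitude (negative peak < −40 µV, peak-to-peak > 75 µV)
or adaptively (each > 2× the per-channel candidate mean).

**Coupling.** With SO phase φ from the analytic signal of the 0.5–4 Hz
trace (0° = positive peak), coupling is summarized by the overlap rate, the
inter-trial phase clustering magnitude R = |⟨e^{iφ_k}⟩| over spindle peaks,
and the mean angle — each standardized against event-count-preserving
shuffle surrogates into Z-scores. Instantaneous spindle frequency
(filter–Hilbert) is summarized over 5 progression quintiles × 18 SO-phase
bins, with Mardia's circular–linear correlation and cubic/harmonic
regression R².

**Spectra and connectivity.** Welch power (4-s Tukey(0.5) segments, 50%
overlap, 0.25 Hz bins, 0.5–20 Hz), band power, log–log spectral slope,
magnitude-squared coherence, and the Nolte phase slope index
PSI = Im Σ_f C*(f) C(f+δf) over 5 Hz windows at 3–20 Hz centers,
jackknife-normalized per epoch, with per-channel net PSI.

**Statistics.** Per channel/metric: logit(group) ~ metric + age + sex with
Wald tests and residualized standardized effect sizes; family-wise error
across channels controlled by the min-p (max-statistic) permutation scheme,
adjusted p = (R_C + 1)/(R + 1). Metric grids are reduced by SVD
(A = UΣVᵀ) into principal spectral components; components with ≥ 1%
variance and group p < 0.01 feed a joint logistic classifier whose AUC and
Nagelkerke R² are optimism-corrected by bootstrap, and which transfers to
new cohorts via the projection U_B = (B − μ_train) V Σ⁻¹.

## Worked example

```python
import numpy as np
from sleepmicro import synth, spindles, slowosc, coupling as cpl

bg = synth.BackgroundSpec(n_channels=1, duration=1200, rms=20, seed=7)
rec, stages, truth = synth.simulate_subject(
    bg,
    so=synth.SOSpec(density=6.0),
    fast=synth.SpindleSpec(center_freq=15.0, density=3.0,
                           coupling_phase=240.0, coupling_kappa=20.0),
    seed=7,
)

mask = stages.clean_sample_mask(rec.fs, rec.n_samples)
cfg = spindles.SpindleDetectorConfig(center_freq=15.0)
evs = spindles.detect_spindles(rec.data[0], rec.fs, mask, cfg)
evs = spindles.qc_spindles(evs, rec.data[0], rec.fs, mask, cfg)
m = spindles.spindle_metrics(evs, stages.minutes())
print(f"fast-spindle density {m.density:.2f}/min (truth "
      f"{len(truth.spindles) / stages.minutes():.2f}/min)")

sos = slowosc.detect_so(rec.data[0], rec.fs, mask,
                        slowosc.SODetectorConfig(mode="absolute"))
phase = cpl.so_phase(rec.data[0], rec.fs)
raw = cpl.coupling_metrics(evs, sos, phase, rec.fs)
res = cpl.surrogate_normalize(raw, evs, sos, phase, mask, rec.fs,
                              cpl.SurrogateConfig(n_shuffles=1000, seed=1))
print(f"coupling angle {raw.mean_angle:.1f} deg, ITPC {raw.magnitude_raw:.2f}, "
      f"magnitude Z {res.magnitude_z:.1f}")
```

prints (seed 7):

```
fast-spindle density 3.30/min (truth 3.55/min)
coupling angle 240.1 deg, ITPC 0.92, magnitude Z 11.3
```

i.e. the detector recovers the injected density to within a few percent,
and the surrogate-normalized coupling statistic flags the injected 240°
phase preference (Z ≫ 2) at essentially the generated angle. A
command-line layer covers the same flow on files:
`sleepmicro simulate | detect-spindles | detect-so | couple | psd | psi`.

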