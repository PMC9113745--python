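# Methods

This note documents the models, estimators, and numerical choices behind
`sleepmicro`, and what the synthetic-data tests do and do not establish
about behavior on clinical recordings.

## Signals and preprocessing

All analyses operate on multichannel EEG in microvolts at 200 Hz.
`io.preprocess` re-references to linked mastoids (signal minus the mean of
the two mastoid channels), resamples with a polyphase filter, and bandpasses
0.3–35 Hz with a zero-phase FIR (forward–backward application of a
linear-phase `firwin` design, ~3 cycles of the low edge long). A zero-phase
filter is used throughout because SO morphology metrics (slope, peak times)
and all phase estimates are corrupted by asymmetric group delay; the cost is
edge transients over roughly one filter length at the recording boundaries.

### Artifact pipeline

Cleaning runs in three passes on 30-s epochs, separately within each sleep
stage, using the Hjorth descriptors activity (variance), mobility, and
complexity. The derivative underlying mobility/complexity is the plain
first difference; for a tone at frequency f this gives mobility
2·sin(πf/fs) ≈ 2πf/fs. The constant scale is irrelevant because every
decision compares mobilities against each other.

1. **Bad channels** — within each epoch, each channel's three Hjorth values
   are z-scored across channels (mean/SD); a channel flagged (any
   parameter, |z| > 2) in more than 30% of its stage epochs is rebuilt for
   the whole recording by spherical-spline interpolation. If more than 25%
   of channels qualify the run aborts, since interpolation from a
   minority of good channels is unreliable.
2. **Outlier cells** — epoch × channel Hjorth values are z-scored against
   the pooled distribution over all epochs and channels of the stage
   (|z| > 4), and cells with peak amplitude > 500 µV or > 10% flat/clipped
   samples are added; flagged cells are interpolated for that epoch (or the
   epoch is dropped when fewer than 4 clean channels remain or positions
   are unavailable).
3. **Global drop** — within each channel, epochs with |z| > 4 against that
   channel's own epochs are flagged, and a flagged epoch is removed for
   *all* channels; the pass runs twice. The retained epoch set is therefore
   identical across channels.

A structural property worth knowing: the pass-1 rule uses the plain
cross-channel mean and SD, so when a fraction k/n > ~20% of channels carry
an arbitrarily large artifact of the same kind, they mask one another (the
z-score of a large outlier tends to √((n−k)/k) < 2). The 25% abort
threshold is therefore reachable only when channels fail in *different*
Hjorth parameters; heavily contaminated montages should be screened before
this pipeline. We keep mean/SD (rather than robust location/scale) because
that is the procedure being modeled.

Spherical-spline interpolation uses the standard thin-plate formulation on
the unit sphere (stiffness m = 4, 20 Legendre terms, 1e-8 ridge), solving
the constrained system with a constant offset and evaluating the fitted
spline at the bad-channel positions.

### EDF

EDF files are read through MNE. Writing uses an in-package 16-bit EDF
writer (1-s records, physical dimension µV, per-channel physical range from
the data); round trips are accurate to one quantization step of the
physical range.

## Spindle detection

The detector magnitude is a single-frequency complex Morlet transform at
the target frequency (11 Hz for slow, 15 Hz for fast spindles) with a
Gaussian envelope of σ_t = cycles/(2π f_c); the default 7 cycles gives a
spectral σ_f ≈ 2.1 Hz at 15 Hz, enough to separate the two classes
(cross-talk in simulations < 15%, usually zero). The magnitude is smoothed
with a 0.1-s moving average and thresholded at multiples of its mean over
clean N2 samples — 4.5× for ≥ 0.3 s (core) inside 2× for ≥ 0.5 s (flank).
Intervals > 3 s are rejected; consecutive intervals within 0.5 s are merged
unless the result would exceed 3 s. Because thresholds are mean-relative,
detection is exactly invariant to rescaling the signal.

Detectability has a hard floor worth stating: the mean smoothed magnitude
of band-limited Gaussian background equals ~1.25× the background's rms
through the wavelet's band (Rayleigh envelope mean), so a sustained
sinusoid only crosses the 4.5×-mean core threshold when its amplitude
exceeds ≈ 5.6× the background sigma-band rms. Clear spindles in real N2
data sit well above this (their p2p amplitude is an order of magnitude
above sigma-band background rms); simulated events near the floor are
invisible to this detector family by construction, not by implementation.

QC: for each event, Welch band power in the event window is divided by the
corresponding stage-wide band power; the event is kept iff the sigma ratio
(target ± 2 Hz) is at least the delta (0.5–4), theta (4–8), and beta
(15–30 Hz) ratios. Band edges are package choices; QC behavior near exact
spectral flatness is a coin flip by construction (a perfectly flat
broadband artifact raises all bands equally).

Per-event metrics: amplitude is the maximal consecutive peak-to-trough
difference of the ±2 Hz bandpassed waveform and the event peak is the
center of that cycle; ISA is the per-sample sum of mean-normalized smoothed
magnitudes divided by fs; observed frequency is 1/(2 × mean zero-crossing
interval) of the bandpassed event; chirp is the implied frequency of the
second half of the interval sequence minus the first half, splitting the
*interval list* symmetrically (middle interval dropped when odd) so that
time-reversing a waveform flips the sign exactly. Events with fewer than
~4 crossings per half are excluded from chirp averaging.

## SO detection

Candidates are delimited by zero crossings of the 0.3–4 Hz zero-phase
filtered trace: an event starts at a positive-to-negative crossing, the
negative half-wave must last 0.3–1.5 s, and the positive peak must occur
within 1 s of the up-crossing (the event ends at the next
positive-to-negative crossing). The crossing-to-peak reading of the
positive-half criterion is deliberate: requiring the *entire* positive
half-wave to close within 1 s makes detection depend on background activity
after the event (on sparse signals the closing crossing can be arbitrarily
late), whereas the peak-latency criterion is a property of the event
itself. Amplitude filtering is absolute (negative peak < −40 µV and p2p
> 75 µV) or adaptive (negative-peak magnitude and p2p each > 2× the mean
over all temporal-criteria-passing candidates of that channel; candidates,
not final events, define the means). Adaptive mode is scale-equivariant;
absolute mode is not; both are polarity-sensitive, which is why signal
polarity conventions matter when comparing cohorts. The upward slope is
|negative peak| divided by the time from the negative peak to the next zero
crossing; metrics are measured on the 0.3–4 Hz trace, which attenuates
sharp half-sine peaks by roughly 10%.

## Coupling and phase/frequency modulation

SO phase comes from the analytic signal (Hilbert) of the 0.5–4 Hz filtered
trace, expressed in degrees with 0° at the SO positive peak, 180° at the
negative peak, and (180°, 360°) on the rising limb — the convention that
places typical fast-spindle coupling near 240°.

Raw coupling per channel: overlap (fraction of spindles whose interval
intersects any SO), ITPC magnitude R = |⟨e^{iφ}⟩| over SO phase at spindle
peaks, and the mean angle. Because overlap and R scale with event counts
and densities, both are standardized against surrogates that preserve the
event counts: the overlap null relocates whole spindles (durations kept)
uniformly within the clean analyzed samples; the magnitude null relocates
spindle peaks uniformly within the union of SO intervals, preserving gross
overlap. Z = (observed − null mean)/null SD; the per-subject empirical p is
(r + 1)/(n + 1) with r the count of null magnitudes ≥ observed (ties count
against significance). Default 10,000 shuffles; calibration tests use 500,
where the null Z is standard normal to within mean ±0.2 and SD 0.8–1.2.

Instantaneous spindle frequency is the filter–Hilbert derivative of
unwrapped phase (±2 Hz around the channel's mean observed frequency),
smoothed over 3 samples. Frequencies are summarized by 5 equal-time
quintiles of each event (quintile means averaged across events), by 18 ×
20° SO-phase bins and by the joint 5 × 18 grid (both pooling spindle
samples). Phase dependence is quantified by Mardia's circular–linear
correlation on the 18 bin means, and by least-squares fits of the joint-
grid cells on (a) a cubic polynomial in quintile index, (b) harmonics
sin(kθ), cos(kθ), k ≤ 3, and (c) their additive union, reporting adjusted
R². Note that chirp plus phase coupling induces a *spurious* phase–
frequency association through the progression–phase correlation; the joint
model separates the two, which is exactly why it exists.

## Spectra and connectivity

Welch PSD: per 30-s epoch, 4-s segments with a Tukey(0.5) taper and 50%
overlap (0.25 Hz bins), averaged within then across epochs; reported over
0.5–20 Hz (79 bins) in µV²/Hz. Band power sums bins × bin width. Spectral
slope is the least-squares slope of log10 power on log10 frequency over the
full grid; a generator exponent s is recovered as −s ± 0.1 for s ≤ 3.

PSI: per epoch, coherency is estimated from Hann-windowed 2-s sub-intervals
(50% overlap) of the 4-s segments (δf = 0.5 Hz), and
PSI(f_c) = Im Σ C*(f) C(f+δf) over the 5 Hz window [f_c − 2.5, f_c + 2.5]
for centers 3–20 Hz. Each epoch's PSI is divided by its jackknife
(leave-one-sub-segment-out) SD, and normalized values are averaged over 20
randomly selected (seeded) clean N2 epochs — all available, with a warning,
when fewer exist. Positive PSI(x→y) means x leads. The pairwise array is
antisymmetric to machine precision; net PSI is the row sum and sums to zero
across channels. Being built on the imaginary part of coherency, PSI is
insensitive to instantaneous mixing: zero-lag mixtures stay within ±2 in
≥ 95% of simulations, while a 25 ms lag in 8–14 Hz content is detected
(> +2 at the 11 Hz center) in ≥ 90%.

## Statistics

Per channel and metric, group status is modeled as
logit(group) ~ metric + age + sex, and the metric's Wald p-value is
reported. The accompanying effect size is a residualized Cohen's d: the
metric is regressed on age and sex, and the case-minus-control difference
in residual means is divided by the pooled residual SD. Values more than
3 SD from the pooled-group mean are removed per channel before modeling
(strict inequality; a value at exactly 3 SD stays).

Multiple testing across channels uses the min-p permutation scheme: group
labels are permuted across subjects (covariates stay with their subjects),
all channels are refit under the *same* relabeling, the minimum null
p-value per replicate is recorded, and the adjusted p for channel C is
(R_C + 1)/(R + 1) with R_C the number of null minima ≤ the observed p
(ties conservative). Default R = 3000; calibration runs use R = 500.
The engine is a vectorized Newton–Raphson IRLS that fits all channels ×
a block of permutations simultaneously (clipped linear predictors, 1e-9
ridge, convergence at 1e-8; non-converged fits are flagged as
quasi-separated and excluded as NaN). It agrees with `statsmodels.Logit`
to ~1e-9 and yields an empirical family-wise error of 5.5% over 200 null
cohorts of 57 correlated channels. Missing channel values are handled
complete-case through zero observation weights.

Cross-metric association residualizes both metrics on group, age, and sex,
removes 3-SD outliers pairwise, and reports Pearson r. Clinical
associations use OLS of metric on clinical score + age + sex.

## Components and prediction

Feature grids (subject × channel×metric or channel×frequency) are
column-centered and decomposed as A = UΣVᵀ; numerically null directions
(singular values < 1e-8 of the largest, including the one removed by
centering) are dropped so out-of-sample projection never divides by ~0.
Components are oriented so each one's largest-magnitude loading is
positive. Components with ≥ 1% of variance are retained; those whose
age/sex-residualized scores show a group difference at p < 0.01 (logistic,
age/sex-adjusted) enter a joint logistic model. New cohorts are projected
with training means, V, and Σ (U_B = (B − μ)VΣ⁻¹), giving exact
self-projection (< 1e-8) and component correspondence across cohorts.

Classifier performance is reported as apparent AUC plus Harrell bootstrap
optimism-corrected AUC and Nagelkerke R²: refit on each resample, evaluate
on the resample and the original sample, average the difference, subtract.
The mean optimism is clipped at zero so the corrected value never exceeds
the apparent one (raw optimism can be marginally negative by Monte-Carlo
noise). Degenerate single-class resamples are skipped. Under null labels
the corrected AUC shrinks to ~0.5 while the apparent AUC stays above it;
with 1-SD effects on a third of the metrics, training-to-fresh-cohort
transfer exceeds AUC 0.75.

## Synthetic data

The generator builds what the detectors assume: a 1/f background
(white-noise FFT shaped by f^(−s/2) from 0.5 Hz up, flat below — real EEG
is high-pass filtered, and an unbounded power law would put nearly all
power below 0.5 Hz), rescaled to a target rms; biphasic SO waveforms
(negative then positive half-sine) at Poisson-spaced non-overlapping
onsets; and Hann- or Gaussian-enveloped spindles with a linear
instantaneous-frequency ramp from f_c − c to f_c + c, which makes the
zero-crossing chirp estimate equal c. Coupled spindles place their envelope
peak at the sample, inside a randomly chosen injected SO, where the *actual
signal's* analytic SO phase is closest to a von Mises draw around the
target phase — so generator-side coupling is measured by exactly the
estimator under test. Events are confined to single N2 epochs (no boundary
straddling), and every injected event is recorded in a ground-truth table.

Defaults are chosen to look like N2 sleep at a central channel: 200 Hz,
20 µV rms, spectral exponent 2 (sigma-band rms ≈ 1.3 µV), SO density
5/min at −60/+50 µV, fast spindles 2.7/min (a typical control-group
density), 1 s, 30 µV p2p, chirp −0.5 Hz, coupling κ = 10 at 240° when
enabled. These are configuration, not ground truth: the study the package
emulates did not publish raw event distributions.

Cohort simulation has two modes. *Metric mode* draws subject × channel
values with unit SD per metric, a shared latent subject factor giving
channel correlation ρ (default 0.5), and a mean shift of the requested
standardized effect size for cases; age and sex are drawn per group. This
is the mode used to validate the statistics and component layers.
*Signal mode* emits full recordings per subject from template specs with
per-group overrides.

What the synthetic tests do not show: real EEG has topographic field
spread (only an optional linear mixing matrix here), non-stationary
background, non-sinusoidal SO shapes, EMG/EOG contamination, and staging
errors. Passing round trips demonstrate internal consistency of the
pipeline and calibration of its null distributions, not field performance.

## Problem sizes in the validation suite

Calibration tests run at sizes chosen to keep Monte-Carlo error comparable
to the tolerance being asserted: 200 cohorts for family-wise error with
R = 500 permutations and 57 channels; 200 seeds × 500 shuffles for the
coupling-Z null; 100 seeds for PSI directionality (5 epochs each); 20
cohorts of n = 60+60 for effect-size recovery (single-cohort d has SD
≈ 0.2, so averaging tests calibration rather than one draw); 10 cohorts
for chance-level transfer AUC. Event round trips use 10–20 min of signal.

## Known limitations

- ISA normalization follows the per-sample stage-mean convention declared
  above; other toolchains may scale it differently, so absolute ISA values
  are comparable only within this package.
- The adaptive SO thresholds are computed over temporal-criteria candidates;
  in signals with few candidates the means are unstable and the detector
  warns.
- The permutation engine assumes the same subjects across channels (missing
  values handled by weights); it does not support per-channel subject sets
  beyond complete-case.
- QC band ratios use Welch estimates on short event windows (high variance);
  near-flat-spectrum artifacts are rejected only in expectation.
- The bootstrap optimism correction inherits the selection-before-
  validation caveat: components are selected by their group association
  before the classifier is corrected, so corrected AUC is still optimistic
  relative to a fully external validation — which is why held-out-cohort
  transfer is reported separately.
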