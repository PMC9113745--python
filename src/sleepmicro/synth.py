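"""Synthetic N2 sleep EEG with ground-truth events and synthetic cohorts.

Signals are built from three layers that mirror what an N2 recording looks
like to the downstream detectors:

* a 1/f background (spectrally shaped white noise, power ∝ f^(-slope)),
* slow oscillations: biphasic half-sine waves (negative then positive
  half-wave) at Poisson-spaced, non-overlapping onsets,
* spindles: Hann/Gaussian-enveloped sinusoids with an optional linear
  instantaneous-frequency ramp (chirp) and optional von-Mises-distributed
  coupling of the envelope peak to the concurrent SO phase.

Every injected event is recorded in a :class:`~sleepmicro.events.GroundTruth`
so detector recall/precision and coupling recovery can be measured exactly.
Cohort simulation additionally provides a metric-level mode that draws
subject × channel metric values with specified standardized group effects,
used to validate the statistics layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._filters import bandpass
from .events import GroundTruth, SOEvent, SpindleEvent
from .io import Recording, StageAnnotation

__all__ = [
    "BackgroundSpec",
    "SpindleSpec",
    "SOSpec",
    "CohortSpec",
    "hemisphere_montage",
    "make_background",
    "inject_so",
    "inject_spindles",
    "simulate_subject",
    "simulate_cohort",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class BackgroundSpec:
    """1/f background EEG: power spectrum ∝ f^(-one_over_f_slope)."""

    n_channels: int = 1
    duration: float = 600.0  # seconds
    fs: float = 200.0
    one_over_f_slope: float = 2.0  # NREM-like 1/f exponent
    rms: float = 20.0  # µV
    seed: int = 0
    mixing: np.ndarray | None = None  # optional (n_channels, n_channels)

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if self.rms < 0:
            raise ValueError("rms must be non-negative")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")


@dataclass
class SpindleSpec:
    """Spindle generator parameters (defaults: fast spindles)."""

    center_freq: float = 15.0  # Hz; 11 for slow spindles
    density: float = 2.7  # events per minute of N2
    duration_mean: float = 1.0  # s
    amplitude: float = 30.0  # µV peak-to-peak at envelope maximum
    chirp: float = -0.5  # Hz, second-half minus first-half implied frequency
    envelope: str = "hann"
    coupling_phase: float | None = None  # degrees, or None for uncoupled
    coupling_kappa: float = 10.0

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be non-negative")
        if not 0.3 < self.duration_mean < 3.0:
            raise ValueError("duration_mean must lie in (0.3, 3.0) s")
        if self.envelope not in ("hann", "gauss"):
            raise ValueError("envelope must be 'hann' or 'gauss'")
        if self.coupling_phase is not None:
            self.coupling_phase = float(self.coupling_phase) % 360.0


@dataclass
class SOSpec:
    """Slow-oscillation generator parameters.

    Half-wave durations are bounded to mirror the detector's temporal
    criteria, so injected events are in principle detectable.
    """

    density: float = 5.0  # events per minute of N2
    neg_peak_amp: float = -60.0  # µV (negative)
    pos_peak_amp: float = 50.0  # µV
    neg_halfwave_dur: float = 0.6  # s
    pos_halfwave_dur: float = 0.6  # s

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be non-negative")
        if self.neg_peak_amp >= 0:
            raise ValueError("neg_peak_amp must be negative")
        if not 0.3 <= self.neg_halfwave_dur <= 1.5:
            raise ValueError("neg_halfwave_dur must lie in [0.3, 1.5] s")
        if self.pos_halfwave_dur > 1.0 or self.pos_halfwave_dur <= 0:
            raise ValueError("pos_halfwave_dur must lie in (0, 1.0] s")


@dataclass
class CohortSpec:
    """Case/control cohort: sizes, standardized effects, and covariates."""

    n_cases: int = 60
    n_controls: int = 60
    effect_sizes: dict = field(default_factory=dict)  # metric -> SD units
    age_distributions: dict = field(
        default_factory=lambda: {"case": (30.0, 8.0), "control": (30.0, 8.0)}
    )
    sex_ratio: float = 0.5  # fraction female
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("cohort sizes must be positive")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Background
# ---------------------------------------------------------------------------

def hemisphere_montage(n: int, seed: int = 7) -> np.ndarray:
    """Quasi-uniform unit-sphere positions on the upper hemisphere."""
    golden = (1 + 5 ** 0.5) / 2
    i = np.arange(n)
    z = (i + 0.5) / n  # upper hemisphere only
    theta = 2 * np.pi * i / golden
    r = np.sqrt(1 - z ** 2)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def make_background(spec: BackgroundSpec) -> Recording:
    """Generate 1/f background EEG by spectral shaping of white noise.

    The white-noise FFT is multiplied by f^(-slope/2) (DC removed), which
    gives direct, exact control of the log-log spectral slope; the result is
    rescaled to the requested per-channel RMS.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    white = rng.standard_normal((spec.n_channels, n))
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs)
    gain = np.zeros_like(freqs)
    # power law holds over the analyzed band (0.5 Hz up); the infra-slow
    # range is held flat, as in high-pass-filtered real EEG — otherwise its
    # power dominates the signal and leaks into the lowest analysis bins
    shaped_f = np.maximum(freqs[1:], 0.5)
    gain[1:] = shaped_f ** (-spec.one_over_f_slope / 2.0)
    shaped = np.fft.irfft(np.fft.rfft(white, axis=-1) * gain, n=n, axis=-1)
    rms = np.sqrt(np.mean(shaped ** 2, axis=-1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        shaped = np.where(rms > 0, shaped / rms * spec.rms, 0.0)
    if spec.rms == 0:
        shaped = np.zeros_like(shaped)
    if spec.mixing is not None:
        shaped = np.asarray(spec.mixing) @ shaped
    names = [f"E{i + 1:02d}" for i in range(spec.n_channels)]
    return Recording(
        data=shaped,
        fs=spec.fs,
        channel_names=names,
        channel_positions=hemisphere_montage(spec.n_channels),
        reference_label="synthetic-average",
    )


# ---------------------------------------------------------------------------
# Event placement
# ---------------------------------------------------------------------------

def _epoch_bounds(rec: Recording, allowed_epochs: np.ndarray | None, epoch_len: float):
    """(start, stop) sample ranges events may occupy, one per usable epoch."""
    spe = int(round(epoch_len * rec.fs))
    if allowed_epochs is None:
        n_ep = max(rec.n_samples // spe, 1)
        spe = min(spe, rec.n_samples)
        allowed_epochs = np.arange(n_ep)
    return [(e * spe, min((e + 1) * spe, rec.n_samples)) for e in allowed_epochs]


def _place_nonoverlapping(rng, durations_samp, bounds, taken, max_tries=2000):
    """Uniform onsets such that each event fits one epoch and none overlap."""
    onsets = []
    for dur in durations_samp:
        usable = [(a, b) for a, b in bounds if b - a >= dur]
        if not usable:
            raise RuntimeError("no epoch long enough to hold an event")
        for _ in range(max_tries):
            a, b = usable[rng.integers(len(usable))]
            onset = int(rng.integers(a, b - dur + 1))
            if all(onset + dur <= s or onset >= e for s, e in taken):
                taken.append((onset, onset + dur))
                onsets.append(onset)
                break
        else:
            raise RuntimeError(
                "event density too high to place non-overlapping events"
            )
    return onsets


def _so_waveform(spec: SOSpec, fs: float) -> np.ndarray:
    n_neg = int(round(spec.neg_halfwave_dur * fs))
    n_pos = int(round(spec.pos_halfwave_dur * fs))
    neg = spec.neg_peak_amp * np.sin(np.pi * np.arange(n_neg) / n_neg)
    pos = spec.pos_peak_amp * np.sin(np.pi * np.arange(n_pos) / n_pos)
    return np.concatenate([neg, pos])


def inject_so(
    rec: Recording,
    spec: SOSpec,
    seed: int = 0,
    allowed_epochs: np.ndarray | None = None,
    epoch_len: float = 30.0,
) -> tuple[Recording, GroundTruth]:
    """Add biphasic SO waveforms at Poisson-spaced, non-overlapping onsets.

    The same waveform is added to every channel (SOs are treated as global
    events). Events never straddle epoch boundaries. The ground truth
    records onset, negative-peak time and amplitudes per event.
    """
    rng = np.random.default_rng(seed)
    out = rec.copy()
    truth = GroundTruth()
    bounds = _epoch_bounds(rec, allowed_epochs, epoch_len)
    minutes = sum(b - a for a, b in bounds) / rec.fs / 60.0
    n_events = rng.poisson(spec.density * minutes)
    if n_events == 0 or spec.density == 0:
        return out, truth
    wave = _so_waveform(spec, rec.fs)
    taken: list[tuple[int, int]] = []
    onsets = _place_nonoverlapping(rng, [len(wave)] * n_events, bounds, taken)
    for onset in sorted(onsets):
        out.data[:, onset : onset + len(wave)] += wave
        n_neg = int(round(spec.neg_halfwave_dur * rec.fs))
        truth.sos.append(
            SOEvent(
                channel="*",
                start=onset / rec.fs,
                stop=(onset + len(wave)) / rec.fs,
                neg_peak_time=(onset + n_neg / 2) / rec.fs,
                neg_peak_amp=spec.neg_peak_amp,
                p2p_amp=spec.pos_peak_amp - spec.neg_peak_amp,
            )
        )
    return out, truth


def _spindle_waveform(spec: SpindleSpec, dur_s: float, fs: float, phase0: float):
    """Enveloped sinusoid with a linear instantaneous-frequency ramp.

    The ramp runs from fc - chirp to fc + chirp so that the implied-frequency
    difference between the second and first half equals ``chirp`` under the
    zero-crossing estimator.
    """
    n = int(round(dur_s * fs))
    t = np.arange(n) / fs
    finst = spec.center_freq + spec.chirp * (2 * t / dur_s - 1.0)
    phase = 2 * np.pi * np.cumsum(finst) / fs + phase0
    if spec.envelope == "hann":
        env = np.hanning(n)
    else:
        env = np.exp(-0.5 * ((t - dur_s / 2) / (dur_s / 6)) ** 2)
    return (spec.amplitude / 2.0) * env * np.sin(phase), finst


def inject_spindles(
    rec: Recording,
    spec: SpindleSpec,
    so_truth: GroundTruth | None = None,
    seed: int = 0,
    allowed_epochs: np.ndarray | None = None,
    epoch_len: float = 30.0,
) -> tuple[Recording, GroundTruth]:
    """Add spindles; optionally lock envelope peaks to SO phase.

    Uncoupled spindles are placed like SOs (Poisson count, uniform onsets,
    no overlap). If ``coupling_phase`` is set, each spindle's envelope peak
    is placed at the sample, within a randomly chosen injected SO, where the
    analytic SO phase of the *actual* signal is closest to a von Mises draw
    around ``coupling_phase``; this makes generator-side coupling directly
    measurable with the coupling analysis.
    """
    rng = np.random.default_rng(seed)
    out = rec.copy()
    truth = GroundTruth()
    if spec.density == 0:
        return out, truth
    bounds = _epoch_bounds(rec, allowed_epochs, epoch_len)
    minutes = sum(b - a for a, b in bounds) / rec.fs / 60.0
    n_events = rng.poisson(spec.density * minutes)
    if n_events == 0:
        return out, truth

    durs = np.clip(
        rng.normal(spec.duration_mean, 0.15 * spec.duration_mean, size=n_events),
        0.4, 2.5,
    )
    durs_samp = np.round(durs * rec.fs).astype(int)
    taken: list[tuple[int, int]] = []

    if spec.coupling_phase is None:
        onsets = _place_nonoverlapping(rng, durs_samp, bounds, taken)
    else:
        if so_truth is None or not so_truth.sos:
            raise ValueError("coupling requested but no SO ground truth given")
        from .coupling import so_phase

        phase = so_phase(out.data[0], rec.fs)
        onsets = []
        kept = []
        for k, dur in enumerate(durs_samp):
            target = math.degrees(
                rng.vonmises(math.radians(spec.coupling_phase), spec.coupling_kappa)
            ) % 360.0
            placed = False
            for _ in range(50):
                so = so_truth.sos[rng.integers(len(so_truth.sos))]
                i0, i1 = int(so.start * rec.fs), int(so.stop * rec.fs)
                seg = phase[i0:i1]
                d = np.abs((seg - target + 180.0) % 360.0 - 180.0)
                peak = i0 + int(np.argmin(d))
                onset = peak - dur // 2
                if onset < 0 or onset + dur > rec.n_samples:
                    continue
                if all(onset + dur <= s or onset >= e for s, e in taken):
                    taken.append((onset, onset + dur))
                    onsets.append(onset)
                    kept.append(k)
                    placed = True
                    break
            if not placed:
                continue
        durs_samp = durs_samp[kept]
        durs = durs[kept]

    for onset, dur_samp, dur_s in zip(onsets, durs_samp, durs):
        wave, finst = _spindle_waveform(spec, dur_s, rec.fs, rng.uniform(0, 2 * np.pi))
        out.data[:, onset : onset + len(wave)] += wave
        truth.spindles.append(
            SpindleEvent(
                channel="*",
                start=onset / rec.fs,
                stop=(onset + len(wave)) / rec.fs,
                peak_time=(onset + len(wave) / 2) / rec.fs,
                target="slow" if spec.center_freq < 13 else "fast",
                amplitude=spec.amplitude,
                obs_freq=spec.center_freq,
                chirp=spec.chirp,
            )
        )
    return out, truth


def simulate_subject(
    background: BackgroundSpec,
    so: SOSpec | None = None,
    slow: SpindleSpec | None = None,
    fast: SpindleSpec | None = None,
    n2_fraction: float = 1.0,
    seed: int = 0,
) -> tuple[Recording, StageAnnotation, GroundTruth]:
    """One synthetic subject: background + SOs + slow/fast spindles.

    Contiguous 30-s epochs; the first ``round(n2_fraction * n_epochs)``
    epochs are labeled N2 and receive all events, the remainder are labeled
    W. Events never straddle epoch boundaries.
    """
    if not 0 < n2_fraction <= 1:
        raise ValueError("n2_fraction must lie in (0, 1]")
    epoch_len = 30.0
    n_epochs = int(background.duration // epoch_len)
    if n_epochs < 1:
        raise ValueError("duration must cover at least one 30-s epoch")

    bg = replace(background, seed=seed * 7919 + background.seed)
    rec = make_background(bg)
    n_n2 = max(1, int(round(n2_fraction * n_epochs)))
    stages = np.array(["N2"] * n_n2 + ["W"] * (n_epochs - n_n2), dtype=object)
    annot = StageAnnotation(stages=stages, epoch_len=epoch_len)
    annot.init_mask(rec.n_channels)
    n2_epochs = np.flatnonzero(stages == "N2")

    truth = GroundTruth()
    if so is not None and so.density > 0:
        rec, so_truth = inject_so(rec, so, seed=seed * 31 + 1, allowed_epochs=n2_epochs)
        truth = truth.merged(so_truth)
    so_truth_for_coupling = truth if truth.sos else None
    for i, spin in enumerate((slow, fast)):
        if spin is not None and spin.density > 0:
            rec, sp_truth = inject_spindles(
                rec, spin, so_truth=so_truth_for_coupling,
                seed=seed * 31 + 2 + i, allowed_epochs=n2_epochs,
            )
            truth = truth.merged(sp_truth)
    return rec, annot, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def simulate_cohort(
    spec: CohortSpec,
    mode: str = "metrics",
    metric_names: list[str] | None = None,
    n_channels: int = 57,
    channel_corr: float = 0.5,
    background: BackgroundSpec | None = None,
    so: SOSpec | None = None,
    slow: SpindleSpec | None = None,
    fast: SpindleSpec | None = None,
    case_overrides: dict | None = None,
    n2_fraction: float = 1.0,
):
    """Simulate a case/control cohort.

    ``mode='metrics'`` draws subject × channel × metric values directly:
    each metric has unit total SD, channels share a latent subject factor
    (pairwise correlation ``channel_corr``), and cases are shifted by the
    requested standardized effect sizes identically on all channels. This is
    the mode the statistics layer is validated against. Returns
    ``(values (n_subjects, n_channels, n_metrics), covariates DataFrame)``.

    ``mode='signals'`` emits a full synthetic recording per subject from the
    template specs, with ``case_overrides`` (e.g. ``{"fast": {"density":
    2.0}}``) applied for case subjects. Returns ``(list of (Recording,
    StageAnnotation, GroundTruth), covariates DataFrame)``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases + spec.n_controls
    group = np.array(["case"] * spec.n_cases + ["control"] * spec.n_controls)
    age = np.empty(n)
    for g in ("case", "control"):
        mu, sd = spec.age_distributions[g]
        sel = group == g
        age[sel] = rng.normal(mu, sd, size=sel.sum())
    sex = np.where(rng.random(n) < spec.sex_ratio, "F", "M")
    covars = pd.DataFrame(
        {"subject": [f"S{i:03d}" for i in range(n)], "group": group,
         "age": age, "sex": sex}
    )

    if mode == "metrics":
        if metric_names is None:
            metric_names = sorted(spec.effect_sizes) or ["metric"]
        unknown = set(spec.effect_sizes) - set(metric_names)
        if unknown:
            raise ValueError(f"unknown metric name(s) in effect_sizes: {unknown}")
        if not 0 <= channel_corr < 1:
            raise ValueError("channel_corr must lie in [0, 1)")
        values = np.empty((n, n_channels, len(metric_names)))
        for m, name in enumerate(metric_names):
            latent = rng.standard_normal(n)
            noise = rng.standard_normal((n, n_channels))
            v = np.sqrt(channel_corr) * latent[:, None] + np.sqrt(1 - channel_corr) * noise
            v[group == "case"] += spec.effect_sizes.get(name, 0.0)
            values[:, :, m] = v
        return values, covars

    if mode != "signals":
        raise ValueError("mode must be 'metrics' or 'signals'")
    background = background or BackgroundSpec()
    subjects = []
    for i in range(n):
        subj_specs = {"so": so, "slow": slow, "fast": fast}
        if group[i] == "case" and case_overrides:
            for key, changes in case_overrides.items():
                if subj_specs.get(key) is not None:
                    subj_specs[key] = replace(subj_specs[key], **changes)
        rec, annot, truth = simulate_subject(
            background, so=subj_specs["so"], slow=subj_specs["slow"],
            fast=subj_specs["fast"], n2_fraction=n2_fraction,
            seed=int(rng.integers(2 ** 31 - 1)),
        )
        subjects.append((rec, annot, truth))
    return subjects, covars
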