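"""Wavelet-based sleep spindle detection and morphology metrics.

Slow (~11 Hz) and fast (~15 Hz) spindles are detected from the temporally
smoothed magnitude of a complex Morlet wavelet transform at the target
center frequency. Candidate events must exceed 2x the channel's mean
coefficient for at least 0.5 s and, within that interval, 4.5x the mean for
at least 0.3 s. Intervals longer than 3 s are rejected; consecutive
intervals separated by less than 0.5 s are merged unless the merged event
would exceed 3 s. A band-ratio QC step then discards events whose relative
increase in delta/theta/beta activity exceeds the relative increase in
sigma activity, so that retained events preferentially reflect sigma-band
bursts rather than broadband artifacts.

All thresholds are relative to the mean coefficient over clean N2 samples,
which makes detection invariant to overall amplitude scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from ._filters import bandpass, moving_average
from .events import SpindleEvent

__all__ = [
    "SpindleDetectorConfig",
    "SpindleChannelMetrics",
    "cwt_magnitude",
    "detect_spindles",
    "qc_spindles",
    "chirp_from_zero_crossings",
    "annotate_chirp",
    "spindle_metrics",
]


@dataclass
class SpindleDetectorConfig:
    center_freq: float = 15.0  # Hz; 11 = slow, 15 = fast
    wavelet_cycles: float = 7.0
    smooth_window: float = 0.1  # s
    core_thresh: float = 4.5  # x mean coefficient
    flank_thresh: float = 2.0
    core_min_dur: float = 0.3  # s
    flank_min_dur: float = 0.5
    max_dur: float = 3.0
    merge_gap: float = 0.5
    halfwidth: float = 2.0  # Hz; waveform band = center_freq ± halfwidth

    def __post_init__(self) -> None:
        if self.core_thresh <= self.flank_thresh:
            raise ValueError("core_thresh must exceed flank_thresh")
        if not self.core_min_dur < self.flank_min_dur < self.max_dur:
            raise ValueError("need core_min_dur < flank_min_dur < max_dur")

    @property
    def target(self) -> str:
        return "slow" if self.center_freq < 13 else "fast"


@dataclass
class SpindleChannelMetrics:
    """Per-channel spindle summary: density plus event-mean morphology."""

    n_events: int
    density: float  # per minute of analyzed N2
    amplitude: float
    isa: float
    duration: float
    obs_freq: float
    chirp: float


def cwt_magnitude(x: np.ndarray, fs: float, cfg: SpindleDetectorConfig) -> np.ndarray:
    """Magnitude of the complex Morlet transform at the target frequency.

    The wavelet's Gaussian envelope has sigma = cycles / (2 pi fc); the
    kernel is L1-normalized so a unit-amplitude tone at fc yields a roughly
    unit steady-state magnitude (the absolute scale is irrelevant to the
    detector, whose thresholds are mean-relative).
    """
    if cfg.center_freq >= fs / 2:
        raise ValueError("center frequency must be below Nyquist")
    sigma_t = cfg.wavelet_cycles / (2 * np.pi * cfg.center_freq)
    half = int(np.ceil(4 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    kernel = np.exp(2j * np.pi * cfg.center_freq * t) * np.exp(-t ** 2 / (2 * sigma_t ** 2))
    kernel *= 2.0 / np.sum(np.abs(kernel.real) + 1e-300)
    return np.abs(sps.fftconvolve(x, kernel, mode="same"))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def detect_spindles(
    x: np.ndarray,
    fs: float,
    n2_mask: np.ndarray,
    cfg: SpindleDetectorConfig | None = None,
    channel: str = "ch",
) -> list[SpindleEvent]:
    """Detect candidate spindles (pre-QC) on one channel.

    ``n2_mask`` is a boolean per-sample mask of clean analyzed samples; the
    mean coefficient defining the thresholds is computed over these samples
    only, and events cannot extend outside them.
    """
    cfg = cfg or SpindleDetectorConfig()
    n2_mask = np.asarray(n2_mask, dtype=bool)
    if n2_mask.shape != x.shape:
        raise ValueError("n2_mask must match signal length")
    if not n2_mask.any():
        raise ValueError("empty analysis mask")

    mag = cwt_magnitude(x, fs, cfg)
    smoothed = moving_average(mag, max(1, int(round(cfg.smooth_window * fs))))
    mean_coef = smoothed[n2_mask].mean()
    if mean_coef <= 0:
        return []

    gated = np.where(n2_mask, smoothed, 0.0)
    flank = gated > cfg.flank_thresh * mean_coef
    core = gated > cfg.core_thresh * mean_coef

    candidates = []
    for a, b in _runs(flank):
        if (b - a) / fs < cfg.flank_min_dur:
            continue
        core_runs = _runs(core[a:b])
        if not any((cb - ca) / fs >= cfg.core_min_dur for ca, cb in core_runs):
            continue
        candidates.append((a, b))

    # reject overlong intervals, then merge near-consecutive ones
    candidates = [(a, b) for a, b in candidates if (b - a) / fs <= cfg.max_dur]
    merged: list[tuple[int, int]] = []
    for a, b in candidates:
        if merged:
            pa, pb = merged[-1]
            if (a - pb) / fs <= cfg.merge_gap and (b - pa) / fs <= cfg.max_dur:
                merged[-1] = (pa, b)
                continue
        merged.append((a, b))

    bp = bandpass(x, fs, cfg.center_freq - cfg.halfwidth, cfg.center_freq + cfg.halfwidth)
    events = []
    for a, b in merged:
        amp, peak = _max_peak_to_peak(bp[a:b], fs)
        isa = float(np.sum(smoothed[a:b] / mean_coef)) / fs
        events.append(
            SpindleEvent(
                channel=channel,
                start=a / fs,
                stop=b / fs,
                peak_time=(a + peak) / fs,
                target=cfg.target,
                amplitude=amp,
                isa=isa,
            )
        )
    return events


def _max_peak_to_peak(w: np.ndarray, fs: float) -> tuple[float, float]:
    """Maximal consecutive peak-to-trough amplitude and its center sample."""
    ext = np.flatnonzero(np.diff(np.sign(np.diff(w))) != 0) + 1
    if len(ext) < 2:
        return float(w.max() - w.min()), float(np.argmax(np.abs(w)))
    diffs = np.abs(np.diff(w[ext]))
    k = int(np.argmax(diffs))
    return float(diffs[k]), float((ext[k] + ext[k + 1]) / 2.0)


def _band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    nper = int(min(len(x), 2 * fs))
    f, p = sps.welch(x, fs=fs, nperseg=nper)
    sel = (f >= band[0]) & (f <= band[1])
    return float(p[sel].mean()) if sel.any() else 0.0


def qc_spindles(
    events: list[SpindleEvent],
    x: np.ndarray,
    fs: float,
    n2_mask: np.ndarray,
    cfg: SpindleDetectorConfig | None = None,
) -> list[SpindleEvent]:
    """Discard events whose non-sigma band increase beats the sigma increase.

    For each event, band power within the event window (Welch) is divided
    by the corresponding mean band power over all clean N2 samples; the
    event is kept iff the sigma-band ratio is at least as large as the
    delta, theta, and beta ratios.
    """
    cfg = cfg or SpindleDetectorConfig()
    if not events:
        return []
    sigma = (cfg.center_freq - cfg.halfwidth, cfg.center_freq + cfg.halfwidth)
    bands = {"delta": (0.5, 4.0), "theta": (4.0, 8.0), "beta": (15.0, 30.0), "sigma": sigma}
    baseline = {
        name: max(_band_power(x[np.asarray(n2_mask, bool)], fs, b), 1e-300)
        for name, b in bands.items()
    }
    kept = []
    for ev in events:
        a, b = int(ev.start * fs), int(ev.stop * fs)
        ratios = {
            name: _band_power(x[a:b], fs, bd) / baseline[name]
            for name, bd in bands.items()
        }
        if all(ratios["sigma"] >= ratios[k] for k in ("delta", "theta", "beta")):
            kept.append(ev)
    return kept


def chirp_from_zero_crossings(
    waveform: np.ndarray, fs: float
) -> tuple[float, float, bool]:
    """Chirp and observed frequency from zero-crossing intervals.

    The implied frequency of a stretch of signal is 1 / (2 x mean interval
    between consecutive zero crossings). Returns ``(chirp, obs_freq,
    valid)`` where chirp = implied frequency of the second half minus the
    first half (negative = deceleration) and ``valid`` is False when either
    half has fewer than 4 crossings.
    """
    w = np.asarray(waveform, dtype=float)
    s = np.sign(w)
    # carry the previous sign across exact zeros
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    idx = np.flatnonzero(s[:-1] * s[1:] < 0)
    if len(idx) < 3:
        return np.nan, np.nan, False
    # sub-sample crossing times by linear interpolation
    tc = (idx + w[idx] / (w[idx] - w[idx + 1])) / fs
    intervals = np.diff(tc)
    obs_freq = 1.0 / (2.0 * np.mean(intervals))
    # split the interval sequence symmetrically (middle interval discarded
    # when the count is odd) so that time reversal flips the sign exactly
    k = len(intervals) // 2
    first = intervals[:k]
    second = intervals[len(intervals) - k :]
    if k < 3:
        return np.nan, obs_freq, False
    f1 = 1.0 / (2.0 * np.mean(first))
    f2 = 1.0 / (2.0 * np.mean(second))
    return f2 - f1, obs_freq, True


def annotate_chirp(
    events: list[SpindleEvent],
    x: np.ndarray,
    fs: float,
    cfg: SpindleDetectorConfig | None = None,
) -> list[SpindleEvent]:
    """Fill ``chirp``/``obs_freq`` from the band-limited event waveform.

    Events are bandpassed to center_freq ± 2 Hz before crossing extraction;
    raw-signal crossings would be dominated by background activity.
    """
    cfg = cfg or SpindleDetectorConfig()
    if not events:
        return events
    bp = bandpass(x, fs, cfg.center_freq - cfg.halfwidth, cfg.center_freq + cfg.halfwidth)
    for ev in events:
        a, b = int(ev.start * fs), int(ev.stop * fs)
        ev.chirp, ev.obs_freq, ev.chirp_valid = chirp_from_zero_crossings(bp[a:b], fs)
    return events


def spindle_metrics(events: list[SpindleEvent], minutes: float) -> SpindleChannelMetrics:
    """Aggregate per-channel metrics; means are NaN when no event qualifies."""
    if minutes <= 0:
        raise ValueError("minutes analyzed must be positive")
    n = len(events)
    if n == 0:
        return SpindleChannelMetrics(0, 0.0, np.nan, np.nan, np.nan, np.nan, np.nan)

    def _mean(vals):
        vals = [v for v in vals if v is not None and np.isfinite(v)]
        return float(np.mean(vals)) if vals else np.nan

    return SpindleChannelMetrics(
        n_events=n,
        density=n / minutes,
        amplitude=_mean(e.amplitude for e in events),
        isa=_mean(e.isa for e in events),
        duration=_mean(e.duration for e in events),
        obs_freq=_mean(e.obs_freq for e in events),
        chirp=_mean(e.chirp for e in events if e.chirp_valid),
    )
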