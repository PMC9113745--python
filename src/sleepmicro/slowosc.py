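"""Slow-oscillation detection by zero-crossing criteria.

The signal is bandpassed to 0.3–4 Hz (zero-phase FIR) and candidate SOs are
delimited by zero crossings: an event starts at a positive-to-negative
crossing, its negative half-wave must last 0.3–1.5 s, and the positive peak
must follow the up-crossing within 1 s (the event ends at the next
positive-to-negative crossing). Amplitude filtering then runs in one of two
modes: *absolute* (negative peak below −40 µV and peak-to-peak above 75 µV)
or *adaptive* (negative-peak magnitude and peak-to-peak amplitude each above
twice the mean over all temporal-criteria-passing candidates for that
channel). The adaptive mode is scale-equivariant; the absolute mode is not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._filters import bandpass
from .events import SOEvent

__all__ = ["SODetectorConfig", "SOChannelMetrics", "detect_so", "so_metrics"]


@dataclass
class SODetectorConfig:
    band: tuple[float, float] = (0.3, 4.0)
    neg_halfwave_dur: tuple[float, float] = (0.3, 1.5)  # s
    pos_halfwave_max: float = 1.0  # s
    mode: str = "adaptive"
    abs_neg_thresh: float = -40.0  # µV
    abs_p2p_thresh: float = 75.0  # µV
    adaptive_mult: float = 2.0  # x per-channel candidate mean

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "adaptive"):
            raise ValueError("mode must be 'absolute' or 'adaptive'")
        if self.neg_halfwave_dur[0] <= 0 or self.pos_halfwave_max <= 0:
            raise ValueError("duration bounds must be positive")


@dataclass
class SOChannelMetrics:
    n_events: int
    density: float  # per minute analyzed
    neg_peak_amp: float
    p2p_amp: float
    duration: float
    up_slope: float


def detect_so(
    x: np.ndarray,
    fs: float,
    n2_mask: np.ndarray,
    cfg: SODetectorConfig | None = None,
    channel: str = "ch",
) -> list[SOEvent]:
    """Detect slow oscillations on one channel within the clean-N2 mask."""
    cfg = cfg or SODetectorConfig()
    n2_mask = np.asarray(n2_mask, dtype=bool)
    if n2_mask.shape != x.shape:
        raise ValueError("n2_mask must match signal length")
    filt = bandpass(x, fs, cfg.band[0], cfg.band[1])

    s = np.sign(filt)
    if not (s != 0).any():
        if cfg.mode == "adaptive":
            warnings.warn("no SO candidates; adaptive thresholds undefined", stacklevel=2)
        return []
    if (s == 0).any():
        # carry the previous sign across exact zeros (forward fill)
        idx = np.arange(len(s))
        valid = s != 0
        fill = np.maximum.accumulate(np.where(valid, idx, -1))
        s = np.where(fill >= 0, s[np.maximum(fill, 0)], s[np.argmax(valid)])
    down = np.flatnonzero((s[:-1] > 0) & (s[1:] < 0))  # positive -> negative
    up = np.flatnonzero((s[:-1] < 0) & (s[1:] > 0))

    candidates: list[SOEvent] = []
    for d in down:
        nxt_up = up[up > d]
        if not len(nxt_up):
            continue
        u = nxt_up[0]
        neg_dur = (u - d) / fs
        if not cfg.neg_halfwave_dur[0] <= neg_dur <= cfg.neg_halfwave_dur[1]:
            continue
        nxt_down = down[down > u]
        if not len(nxt_down):
            continue
        d2 = nxt_down[0]
        # positive peak must follow the up-crossing within pos_halfwave_max
        pos_seg = filt[u : d2 + 1]
        kp = int(np.argmax(pos_seg))
        if kp / fs > cfg.pos_halfwave_max:
            continue
        if not n2_mask[d : d2 + 1].all():
            continue
        seg_neg = filt[d : u + 1]
        k = int(np.argmin(seg_neg))
        neg_peak = float(seg_neg[k])
        pos_peak = float(pos_seg[kp])
        rise = (u - (d + k)) / fs
        candidates.append(
            SOEvent(
                channel=channel,
                start=d / fs,
                stop=d2 / fs,
                neg_peak_time=(d + k) / fs,
                neg_peak_amp=neg_peak,
                p2p_amp=pos_peak - neg_peak,
                up_slope=abs(neg_peak) / rise if rise > 0 else np.nan,
            )
        )

    if cfg.mode == "absolute":
        return [
            ev for ev in candidates
            if ev.neg_peak_amp < cfg.abs_neg_thresh and ev.p2p_amp > cfg.abs_p2p_thresh
        ]
    if not candidates:
        warnings.warn("no SO candidates; adaptive thresholds undefined", stacklevel=2)
        return []
    mean_neg = np.mean([abs(ev.neg_peak_amp) for ev in candidates])
    mean_p2p = np.mean([ev.p2p_amp for ev in candidates])
    return [
        ev for ev in candidates
        if abs(ev.neg_peak_amp) > cfg.adaptive_mult * mean_neg
        and ev.p2p_amp > cfg.adaptive_mult * mean_p2p
    ]


def so_metrics(events: list[SOEvent], minutes: float) -> SOChannelMetrics:
    """Per-channel SO density and mean morphology (NaN means if no events)."""
    if minutes <= 0:
        raise ValueError("minutes analyzed must be positive")
    if not events:
        return SOChannelMetrics(0, 0.0, np.nan, np.nan, np.nan, np.nan)
    return SOChannelMetrics(
        n_events=len(events),
        density=len(events) / minutes,
        neg_peak_amp=float(np.mean([e.neg_peak_amp for e in events])),
        p2p_amp=float(np.mean([e.p2p_amp for e in events])),
        duration=float(np.mean([e.duration for e in events])),
        up_slope=float(np.nanmean([e.up_slope for e in events])),
    )
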