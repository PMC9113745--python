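"""Event records shared by the detectors and the synthetic generator."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class SpindleEvent:
    """A detected (or injected) sleep spindle.

    Times are in seconds from recording start. ``target`` distinguishes the
    slow (~11 Hz) from the fast (~15 Hz) detector. ``isa`` is integrated
    spindle activity: the per-sample sum of mean-normalized wavelet
    coefficient magnitudes over the event, divided by the sampling rate.
    ``chirp`` is the implied frequency of the second half minus the first
    half (negative = within-event deceleration).
    """

    channel: str
    start: float
    stop: float
    peak_time: float
    target: str = "fast"
    amplitude: float | None = None  # µV peak-to-peak
    isa: float | None = None
    obs_freq: float | None = None
    chirp: float | None = None
    chirp_valid: bool = True

    @property
    def duration(self) -> float:
        return self.stop - self.start

    def overlaps(self, other_start: float, other_stop: float) -> bool:
        return self.start <= other_stop and other_start <= self.stop


@dataclass
class SOEvent:
    """A detected (or injected) slow oscillation.

    The event spans the negative half-wave followed by the positive
    half-wave, delimited by zero crossings of the 0.3–4 Hz filtered trace.
    ``up_slope`` is the mean slope from the negative peak to the following
    zero crossing, in µV/s.
    """

    channel: str
    start: float
    stop: float
    neg_peak_time: float
    neg_peak_amp: float  # µV, negative
    p2p_amp: float
    up_slope: float | None = None

    @property
    def duration(self) -> float:
        return self.stop - self.start


@dataclass
class GroundTruth:
    """Injected events plus any per-subject true metric values."""

    spindles: list[SpindleEvent] = field(default_factory=list)
    sos: list[SOEvent] = field(default_factory=list)
    true_metrics: dict = field(default_factory=dict)

    def merged(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            spindles=self.spindles + other.spindles,
            sos=self.sos + other.sos,
            true_metrics={**self.true_metrics, **other.true_metrics},
        )
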