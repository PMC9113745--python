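"""SO–spindle temporal coupling and intra-spindle phase/frequency modulation.

Coupling has three raw ingredients per channel: the proportion of spindles
that grossly overlap an SO; the inter-trial phase clustering (ITPC, the
length of the mean unit phasor) of SO phase at spindle peaks; and the mean
coupling angle. SO phase comes from the analytic signal of the 0.5–4 Hz
filtered trace with 0° at the SO positive peak, 180° at the negative peak,
and 180–360° on the rising limb.

Because overlap and ITPC depend on event densities, both are standardized
against shuffle surrogates that preserve the event counts: the overlap null
relocates whole spindles uniformly within the clean analyzed samples, and
the magnitude null relocates spindle peaks uniformly within the union of SO
intervals (preserving gross overlap). The reported Z-scores are
(observed − null mean) / null SD.

Intra-spindle instantaneous frequency (filter–Hilbert) is summarized by
spindle progression quintile, by 18 × 20° SO phase bins, and jointly; the
phase dependence is quantified with the Mardia circular–linear correlation
on the 18 bin means, and with least-squares fits of binned frequency on a
cubic progression basis, a third-order harmonic phase basis, and their
additive union.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._filters import analytic_phase_deg, bandpass, moving_average
from .events import SOEvent, SpindleEvent

__all__ = [
    "CouplingResult",
    "SurrogateConfig",
    "PhaseFreqResult",
    "so_phase",
    "coupling_metrics",
    "surrogate_normalize",
    "instantaneous_frequency",
    "phase_freq_profiles",
    "circ_linear_corr",
    "fit_freq_model",
]

N_PHASE_BINS = 18
N_QUINTILES = 5
PHASE_BIN_CENTERS = np.arange(N_PHASE_BINS) * 20.0 + 10.0


@dataclass
class CouplingResult:
    n_spindles: int
    overlap_raw: float
    magnitude_raw: float
    mean_angle: float  # degrees
    overlap_z: float | None = None
    magnitude_z: float | None = None
    subject_p: float | None = None


@dataclass
class SurrogateConfig:
    n_shuffles: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shuffles < 1:
            raise ValueError("need at least one shuffle")


@dataclass
class PhaseFreqResult:
    freq_by_quintile: np.ndarray  # (5,)
    freq_by_phase_bin: np.ndarray  # (18,)
    joint: np.ndarray  # (5, 18), NaN where empty
    circ_lin_r: float
    model_r2: dict = field(default_factory=dict)


def so_phase(x: np.ndarray, fs: float) -> np.ndarray:
    """Per-sample SO phase in degrees [0, 360), filter–Hilbert on 0.5–4 Hz."""
    return analytic_phase_deg(bandpass(x, fs, 0.5, 4.0))


def coupling_metrics(
    spindle_events: list[SpindleEvent],
    so_events: list[SOEvent],
    phase: np.ndarray,
    fs: float,
) -> CouplingResult:
    """Raw overlap, ITPC magnitude, and mean coupling angle for one channel."""
    n = len(spindle_events)
    if n == 0:
        return CouplingResult(0, np.nan, np.nan, np.nan)
    so_iv = [(s.start, s.stop) for s in so_events]
    overlap = np.mean([
        any(ev.start <= b and a <= ev.stop for a, b in so_iv) for ev in spindle_events
    ])
    peaks = np.clip(
        np.round([ev.peak_time * fs for ev in spindle_events]).astype(int),
        0, len(phase) - 1,
    )
    phasors = np.exp(1j * np.radians(phase[peaks]))
    mean_vec = phasors.mean()
    return CouplingResult(
        n_spindles=n,
        overlap_raw=float(overlap),
        magnitude_raw=float(np.abs(mean_vec)),
        mean_angle=float(np.degrees(np.angle(mean_vec)) % 360.0),
    )


def _mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def surrogate_normalize(
    raw: CouplingResult,
    spindle_events: list[SpindleEvent],
    so_events: list[SOEvent],
    phase: np.ndarray,
    n2_mask: np.ndarray,
    fs: float,
    cfg: SurrogateConfig | None = None,
) -> CouplingResult:
    """Add surrogate-normalized Z-scores and the per-subject empirical p.

    subject_p = (r + 1) / (n_shuffles + 1) with r the number of magnitude
    nulls at least as large as the observed ITPC.
    """
    cfg = cfg or SurrogateConfig()
    rng = np.random.default_rng(cfg.seed)
    n = len(spindle_events)
    out = CouplingResult(**vars(raw))
    if n == 0 or not so_events:
        return out
    n2_mask = np.asarray(n2_mask, dtype=bool)

    # --- overlap null: whole spindles relocated uniformly in clean samples
    so_cover = np.zeros(len(phase) + 1)
    for s in so_events:
        so_cover[int(s.start * fs) : int(s.stop * fs) + 1] = 1.0
    so_csum = np.concatenate(([0.0], np.cumsum(so_cover)))
    runs = _mask_runs(n2_mask)
    durs = np.round([ev.duration * fs for ev in spindle_events]).astype(int)
    null_overlap = np.empty(cfg.n_shuffles)
    starts_by_dur = {}
    for d in np.unique(durs):
        opts = np.concatenate(
            [np.arange(a, b - d) for a, b in runs if b - a > d] or [np.array([], int)]
        )
        starts_by_dur[d] = opts
    if all(len(v) for v in starts_by_dur.values()):
        hits = np.zeros((cfg.n_shuffles, n), dtype=bool)
        for j, d in enumerate(durs):
            opts = starts_by_dur[d]
            draw = opts[rng.integers(len(opts), size=cfg.n_shuffles)]
            hits[:, j] = (so_csum[draw + d + 1] - so_csum[draw]) > 0
        null_overlap = hits.mean(axis=1)
        sd = null_overlap.std()
        out.overlap_z = (
            float((raw.overlap_raw - null_overlap.mean()) / sd) if sd > 0 else None
        )

    # --- magnitude null: peaks relocated uniformly within the SO union
    pool = np.flatnonzero(so_cover[:-1] > 0)
    if len(pool):
        draws = pool[rng.integers(len(pool), size=(cfg.n_shuffles, n))]
        phasors = np.exp(1j * np.radians(phase[draws]))
        null_mag = np.abs(phasors.mean(axis=1))
        sd = null_mag.std()
        out.magnitude_z = (
            float((raw.magnitude_raw - null_mag.mean()) / sd) if sd > 0 else None
        )
        r = int(np.sum(null_mag >= raw.magnitude_raw))
        out.subject_p = (r + 1) / (cfg.n_shuffles + 1)
    return out


def instantaneous_frequency(x: np.ndarray, fs: float, mean_freq: float) -> np.ndarray:
    """Per-sample instantaneous frequency (Hz) by filter–Hilbert.

    Bandpass ±2 Hz around the channel's mean observed spindle frequency,
    then the derivative of the unwrapped analytic phase, smoothed over 3
    samples.
    """
    from scipy.signal import hilbert

    bp = bandpass(x, fs, mean_freq - 2.0, mean_freq + 2.0)
    phase = np.unwrap(np.angle(hilbert(bp)))
    freq = np.gradient(phase) * fs / (2 * np.pi)
    return moving_average(freq, 3)


def phase_freq_profiles(
    events: list[SpindleEvent],
    freq: np.ndarray,
    phase: np.ndarray,
    fs: float,
) -> PhaseFreqResult:
    """Summaries of spindle frequency by progression quintile and SO phase.

    Quintiles are equal-time fifths of each event. Quintile means are
    averaged across events (each spindle contributes one value per
    quintile); phase-bin and joint means pool all spindle samples.
    """
    if not events:
        raise ValueError("need at least one event")
    per_event_quint = []
    bin_sum = np.zeros(N_PHASE_BINS)
    bin_cnt = np.zeros(N_PHASE_BINS)
    joint_sum = np.zeros((N_QUINTILES, N_PHASE_BINS))
    joint_cnt = np.zeros((N_QUINTILES, N_PHASE_BINS))
    for ev in events:
        a, b = int(ev.start * fs), int(ev.stop * fs)
        if b - a < N_QUINTILES:
            continue
        f = freq[a:b]
        q = np.minimum((np.arange(b - a) * N_QUINTILES) // (b - a), N_QUINTILES - 1)
        p = np.minimum((phase[a:b] // 20.0).astype(int), N_PHASE_BINS - 1)
        per_event_quint.append(np.bincount(q, f, N_QUINTILES) / np.bincount(q, None, N_QUINTILES))
        np.add.at(bin_sum, p, f)
        np.add.at(bin_cnt, p, 1)
        np.add.at(joint_sum, (q, p), f)
        np.add.at(joint_cnt, (q, p), 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        by_quintile = np.mean(per_event_quint, axis=0)
        by_bin = np.where(bin_cnt > 0, bin_sum / np.maximum(bin_cnt, 1), np.nan)
        joint = np.where(joint_cnt > 0, joint_sum / np.maximum(joint_cnt, 1), np.nan)
    r = circ_linear_corr(PHASE_BIN_CENTERS, by_bin)
    result = PhaseFreqResult(
        freq_by_quintile=by_quintile,
        freq_by_phase_bin=by_bin,
        joint=joint,
        circ_lin_r=r,
    )
    try:
        result.model_r2 = fit_freq_model(joint)
    except ValueError:
        result.model_r2 = {}
    return result


def circ_linear_corr(theta_deg: np.ndarray, values: np.ndarray) -> float:
    """Mardia circular–linear correlation between angles and values, in [0, 1].

    r² = (r_xc² + r_xs² − 2 r_xc r_xs r_cs) / (1 − r_cs²) with r_xc =
    corr(v, cos θ), r_xs = corr(v, sin θ), r_cs = corr(cos θ, sin θ).
    Constant values give r = 0.
    """
    theta = np.radians(np.asarray(theta_deg, dtype=float))
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v)
    theta, v = theta[ok], v[ok]
    if len(v) < 3:
        raise ValueError("need at least 3 non-missing bins")
    if np.ptp(v) == 0:
        return 0.0
    c, s = np.cos(theta), np.sin(theta)
    rxc = np.corrcoef(v, c)[0, 1]
    rxs = np.corrcoef(v, s)[0, 1]
    rcs = np.corrcoef(c, s)[0, 1]
    num = rxc ** 2 + rxs ** 2 - 2 * rxc * rxs * rcs
    r2 = num / (1 - rcs ** 2)
    return float(np.sqrt(max(r2, 0.0)))


def _adj_r2(y: np.ndarray, design: np.ndarray) -> float:
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    n, p = design.shape
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("constant response; R² undefined")
    r2 = 1 - ss_res / ss_tot
    return 1 - (1 - r2) * (n - 1) / (n - p)


def fit_freq_model(joint: np.ndarray) -> dict:
    """Adjusted R² of binned frequency on progression, phase, and both.

    Observations are the non-missing cells of the 5 × 18 joint matrix.
    Progression basis: cubic polynomial in quintile index. Phase basis:
    circular harmonics sin(kθ), cos(kθ) for k = 1..3. Combined: their
    additive union.
    """
    joint = np.asarray(joint, dtype=float)
    qi, pi = np.nonzero(np.isfinite(joint))
    y = joint[qi, pi]
    if len(y) < 12:
        raise ValueError("too few non-missing cells to fit")
    q = qi + 1.0
    theta = np.radians(PHASE_BIN_CENTERS[pi])
    ones = np.ones_like(y)
    prog = np.column_stack([ones, q, q ** 2, q ** 3])
    harm = np.column_stack(
        [ones] + [f(k * theta) for k in (1, 2, 3) for f in (np.sin, np.cos)]
    )
    both = np.column_stack([prog, harm[:, 1:]])
    return {
        "progression": _adj_r2(y, prog),
        "phase": _adj_r2(y, harm),
        "combined": _adj_r2(y, both),
    }
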