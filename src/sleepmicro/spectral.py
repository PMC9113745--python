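"""Welch spectra, band power, spectral slope, coherence, and phase slope index.

Power spectra use Welch's method within 30-s epochs: 4-s segments (0.25 Hz
resolution) with a Tukey (50%) taper and 50% overlap, averaged within and
then across epochs, reported on the 0.5–20 Hz grid (79 bins).

The phase slope index (PSI) estimates directed connectivity from the slope
of cross-spectral phase across a 5 Hz window: PSI = Im Σ_f C*(f) C(f+δf)
with C the complex coherency. Coherency is estimated per epoch from 2-s
sub-intervals (50% overlap) of 4-s segments; each epoch's PSI is normalized
by its jackknife (leave-one-sub-segment-out) SD, and the normalized values
are averaged across the analyzed epochs. Positive PSI(x → y) means x
temporally leads y. Imaginary-part-based estimators are insensitive to
instantaneous (zero-lag) mixing such as volume conduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "PSDResult",
    "PSIConfig",
    "PSIResult",
    "welch_psd",
    "band_power",
    "spectral_slope",
    "ms_coherence",
    "psi_pairwise",
    "psi",
    "net_psi",
]


@dataclass
class PSDResult:
    freqs: np.ndarray  # Hz, 0.25 Hz grid
    power: np.ndarray  # (n_channels, n_freqs), µV²/Hz

    @property
    def log_power(self) -> np.ndarray:
        return 10.0 * np.log10(self.power)


@dataclass
class PSIConfig:
    segment_len: float = 4.0  # s
    sub_interval: float = 2.0  # s
    overlap: float = 0.5
    n_epochs: int = 20
    epoch_len: float = 30.0
    centers: np.ndarray = field(default_factory=lambda: np.arange(3.0, 21.0))
    window: float = 5.0  # Hz
    seed: int = 0


def welch_psd(
    data: np.ndarray,
    fs: float,
    epoch_starts: np.ndarray | None = None,
    epoch_len: float = 30.0,
    fmin: float = 0.5,
    fmax: float = 20.0,
) -> PSDResult:
    """Epoch-averaged Welch PSD on the 0.25 Hz grid.

    ``data`` is (n_channels, n_samples); ``epoch_starts`` gives the starting
    sample of each analyzed epoch (default: contiguous tiling).
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    spe = int(round(epoch_len * fs))
    nper = int(round(4.0 * fs))
    if spe < nper:
        raise ValueError("epoch shorter than the 4-s Welch segment")
    if epoch_starts is None:
        epoch_starts = np.arange(0, data.shape[1] - spe + 1, spe)
    if len(epoch_starts) == 0:
        raise ValueError("no epochs to analyze")
    acc = None
    for s in epoch_starts:
        f, p = sps.welch(
            data[:, s : s + spe], fs=fs, window=("tukey", 0.5),
            nperseg=nper, noverlap=nper // 2, axis=-1,
        )
        acc = p if acc is None else acc + p
    power = acc / len(epoch_starts)
    sel = (f >= fmin - 1e-9) & (f <= fmax + 1e-9)
    return PSDResult(freqs=f[sel], power=power[:, sel])


def band_power(psd: PSDResult, band: tuple[float, float]) -> np.ndarray:
    """Per-channel power (µV²) summed over ``band``: Σ bins × 0.25 Hz."""
    sel = (psd.freqs >= band[0]) & (psd.freqs <= band[1])
    if not sel.any():
        raise ValueError(f"band {band} contains no spectral bins")
    width = np.median(np.diff(psd.freqs))
    return psd.power[:, sel].sum(axis=-1) * width


def spectral_slope(psd: PSDResult) -> np.ndarray:
    """Per-channel slope of log10 power on log10 frequency (0.5–20 Hz).

    1/f-like spectra give negative slopes; the generator's exponent s
    corresponds to a fitted slope of −s.
    """
    if psd.freqs.size < 2:
        raise ValueError("need at least two spectral bins")
    lx = np.log10(psd.freqs)
    ly = np.log10(psd.power)
    lx = lx - lx.mean()
    return (ly @ lx) / (lx @ lx)


def ms_coherence(
    x: np.ndarray, y: np.ndarray, fs: float, band: tuple[float, float]
) -> float:
    """Magnitude-squared coherence |S_xy|²/(S_xx S_yy) averaged over a band."""
    if x.shape != y.shape:
        raise ValueError("signals must have identical shape")
    nper = int(round(4.0 * fs))
    f, c = sps.coherence(
        x, y, fs=fs, window=("tukey", 0.5), nperseg=nper, noverlap=nper // 2
    )
    sel = (f >= band[0]) & (f <= band[1])
    if not sel.any():
        raise ValueError("band contains no bins")
    return float(c[sel].mean())


# ---------------------------------------------------------------------------
# Phase slope index
# ---------------------------------------------------------------------------

def _sub_ffts(epoch: np.ndarray, fs: float, cfg: PSIConfig) -> np.ndarray:
    """FFTs of Hann-windowed 2-s sub-intervals of 4-s segments: (nch, m, nf)."""
    nch, spe = epoch.shape
    seg = int(round(cfg.segment_len * fs))
    sub = int(round(cfg.sub_interval * fs))
    seg_step = max(int(seg * (1 - cfg.overlap)), 1)
    sub_step = max(int(sub * (1 - cfg.overlap)), 1)
    win = np.hanning(sub)
    chunks = []
    for s0 in range(0, spe - seg + 1, seg_step):
        for s1 in range(s0, s0 + seg - sub + 1, sub_step):
            chunks.append(epoch[:, s1 : s1 + sub] * win)
    return np.fft.rfft(np.stack(chunks, axis=1), axis=-1)


def _psi_from_ffts(fx: np.ndarray, fy: np.ndarray, freqs: np.ndarray, cfg: PSIConfig):
    """Per-center-frequency normalized PSI for one epoch.

    Jackknife over sub-segments provides the SD used for normalization.
    """
    m = fx.shape[0]
    sxy = fx * np.conj(fy)
    sxx = np.abs(fx) ** 2
    syy = np.abs(fy) ** 2
    sum_xy, sum_xx, sum_yy = sxy.sum(0), sxx.sum(0), syy.sum(0)

    def _psi_line(axy, axx, ayy):
        c = axy / np.sqrt(np.maximum(axx * ayy, 1e-300))
        t = np.conj(c[..., :-1]) * c[..., 1:]
        out = np.empty(axy.shape[:-1] + (len(cfg.centers),))
        for k, fc in enumerate(cfg.centers):
            sel = (freqs[:-1] >= fc - cfg.window / 2) & (
                freqs[1:] <= fc + cfg.window / 2
            )
            out[..., k] = np.imag(t[..., sel].sum(axis=-1))
        return out

    full = _psi_line(sum_xy, sum_xx, sum_yy)
    loo = _psi_line(sum_xy - sxy, sum_xx - sxx, sum_yy - syy)
    sd = np.sqrt((m - 1) / m * ((loo - loo.mean(axis=0)) ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sd > 0, full / sd, 0.0)


def psi_pairwise(
    data: np.ndarray,
    fs: float,
    epoch_starts: np.ndarray | None = None,
    cfg: PSIConfig | None = None,
) -> "PSIResult":
    """Normalized PSI between all channel pairs.

    ``epoch_starts`` lists the starting samples of analyzed clean N2 epochs;
    if more than ``cfg.n_epochs`` are given, a seeded random subset of that
    size is used (all available, with a warning, if fewer).
    """
    import warnings

    cfg = cfg or PSIConfig()
    data = np.atleast_2d(np.asarray(data, dtype=float))
    nch = data.shape[0]
    spe = int(round(cfg.epoch_len * fs))
    if epoch_starts is None:
        epoch_starts = np.arange(0, data.shape[1] - spe + 1, spe)
    epoch_starts = np.asarray(epoch_starts)
    rng = np.random.default_rng(cfg.seed)
    if len(epoch_starts) > cfg.n_epochs:
        epoch_starts = np.sort(rng.choice(epoch_starts, cfg.n_epochs, replace=False))
    elif len(epoch_starts) < cfg.n_epochs:
        warnings.warn(
            f"only {len(epoch_starts)} epochs available (< {cfg.n_epochs}); using all",
            stacklevel=2,
        )
    if len(epoch_starts) == 0:
        raise ValueError("no epochs to analyze")

    sub = int(round(cfg.sub_interval * fs))
    freqs = np.fft.rfftfreq(sub, 1.0 / fs)
    acc = np.zeros((nch, nch, len(cfg.centers)))
    for s in epoch_starts:
        ffts = _sub_ffts(data[:, s : s + spe], fs, cfg)
        for i in range(nch):
            for j in range(i + 1, nch):
                v = _psi_from_ffts(ffts[i], ffts[j], freqs, cfg)
                acc[i, j] += v
                acc[j, i] -= v
    pairwise = acc / len(epoch_starts)
    return PSIResult(centers=np.asarray(cfg.centers, float), pairwise=pairwise)


def psi(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    epoch_starts: np.ndarray | None = None,
    cfg: PSIConfig | None = None,
) -> np.ndarray:
    """Normalized PSI(x → y) per center frequency; positive = x leads y."""
    res = psi_pairwise(np.vstack([x, y]), fs, epoch_starts, cfg)
    return res.pairwise[0, 1]


@dataclass
class PSIResult:
    centers: np.ndarray  # Hz
    pairwise: np.ndarray  # (n_ch, n_ch, n_centers), antisymmetric

    @property
    def net(self) -> np.ndarray:
        return net_psi(self.pairwise)


def net_psi(pairwise: np.ndarray) -> np.ndarray:
    """Per-channel net PSI: the sum of pairwise values involving the channel.

    Positive entries mark net 'sender' channels. Because the pairwise array
    is antisymmetric, the net values sum to zero at every frequency.
    """
    pairwise = np.asarray(pairwise)
    if pairwise.shape[0] != pairwise.shape[1]:
        raise ValueError("pairwise must be square in its first two axes")
    return pairwise.sum(axis=1)
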