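"""Signal containers, EDF and annotation I/O, preprocessing, and artifact QC.

The cleaning pipeline operates on 30-s epochs and proceeds in three passes,
separately within each sleep stage:

1. *Bad channels* — within every epoch, each channel's Hjorth parameters
   (activity, mobility, complexity) are compared across channels; a channel
   flagged in more than ``bad_channel_fraction`` of its epochs is dropped
   and rebuilt by spherical-spline interpolation from the remaining channels.
2. *Outlier epoch/channel cells* — epoch-level Hjorth values are compared
   against the pooled distribution over all epochs and channels at a
   stricter threshold; cells exceeding it, exceeding an absolute amplitude
   ceiling, or containing flat/clipped runs are interpolated per epoch.
3. *Global epoch drop* — within each channel, epochs beyond the threshold
   relative to that channel's own epochs are flagged, and any epoch flagged
   on at least one channel is removed for *all* channels (run twice), so the
   final analytic epoch set is identical across channels.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.polynomial import legendre as npleg
from scipy import signal

from ._filters import bandpass

__all__ = [
    "Recording",
    "StageAnnotation",
    "HjorthTriple",
    "ArtifactConfig",
    "CLEAN",
    "INTERPOLATED",
    "DROPPED",
    "read_edf",
    "write_edf",
    "read_stages_tsv",
    "write_stages_tsv",
    "write_mask_tsv",
    "preprocess",
    "hjorth",
    "artifact_pipeline",
    "interpolate_spherical_spline",
]

CLEAN, INTERPOLATED, DROPPED = 0, 1, 2
_MASK_LABELS = {CLEAN: "clean", INTERPOLATED: "interpolated", DROPPED: "dropped"}


@dataclass
class Recording:
    """Multichannel EEG in microvolts.

    Attributes
    ----------
    data : (n_channels, n_samples) float array, microvolts
    fs : sampling rate, Hz
    channel_names : list of str
    channel_positions : (n_channels, 3) unit-sphere coordinates or None
    reference_label : free-text description of the reference state
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    channel_positions: np.ndarray | None = None
    reference_label: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy())


@dataclass
class StageAnnotation:
    """Per-epoch sleep stages plus a per-epoch/per-channel artifact mask."""

    stages: np.ndarray  # (n_epochs,) of str labels, e.g. W/N1/N2/N3/R
    epoch_len: float = 30.0
    mask: np.ndarray | None = None  # (n_epochs, n_channels) int8

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=object)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=np.int8)
            if self.mask.shape[0] != self.n_epochs:
                raise ValueError("mask rows must match number of epochs")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    def init_mask(self, n_channels: int) -> None:
        if self.mask is None:
            self.mask = np.zeros((self.n_epochs, n_channels), dtype=np.int8)

    def epoch_samples(self, fs: float) -> int:
        return int(round(self.epoch_len * fs))

    def retained_epochs(self, stage: str | None = "N2") -> np.ndarray:
        """Indices of non-dropped epochs, optionally restricted to a stage."""
        keep = np.ones(self.n_epochs, dtype=bool)
        if self.mask is not None:
            keep &= ~(self.mask == DROPPED).any(axis=1)
        if stage is not None:
            keep &= self.stages == stage
        return np.flatnonzero(keep)

    def clean_sample_mask(self, fs: float, n_samples: int, stage: str = "N2") -> np.ndarray:
        """Boolean per-sample mask of retained epochs of ``stage``."""
        out = np.zeros(n_samples, dtype=bool)
        spe = self.epoch_samples(fs)
        for e in self.retained_epochs(stage):
            out[e * spe : min((e + 1) * spe, n_samples)] = True
        return out

    def minutes(self, fs: float | None = None, stage: str = "N2") -> float:
        return len(self.retained_epochs(stage)) * self.epoch_len / 60.0


@dataclass
class HjorthTriple:
    activity: float
    mobility: float
    complexity: float


@dataclass
class ArtifactConfig:
    """Thresholds for the three-pass Hjorth artifact pipeline."""

    bad_channel_epoch_sd: float = 2.0
    bad_channel_fraction: float = 0.30
    epoch_sd: float = 4.0
    max_abs_amp: float = 500.0  # µV
    flat_clip_fraction: float = 0.10
    per_channel_sd: float = 4.0
    final_pass_repeats: int = 1
    max_bad_channel_fraction: float = 0.25

    def __post_init__(self) -> None:
        for name in ("bad_channel_epoch_sd", "bad_channel_fraction", "epoch_sd",
                     "max_abs_amp", "flat_clip_fraction", "per_channel_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# EDF I/O
# ---------------------------------------------------------------------------

def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a :class:`Recording` (microvolts).

    All channels must share one sampling rate; resample heterogeneous files
    before analysis.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    sfreqs = {int(round(raw.info["sfreq"]))}
    if len(sfreqs) != 1:
        raise ValueError("mixed per-channel sampling rates are not supported")
    data = raw.get_data() * 1e6  # V -> µV
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        reference_label="as-recorded",
    )


def _edf_ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a 16-bit EDF file (physical dimension µV, 1-s data records).

    The sampling rate must be an integer. The final partial record, if any,
    is zero-padded.
    """
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    nch = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / fs))
    padded = np.zeros((nch, n_records * fs))
    padded[:, : rec.n_samples] = rec.data

    pmin = np.floor(padded.min(axis=1))
    pmax = np.ceil(padded.max(axis=1))
    flat = pmax - pmin < 1e-9
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767

    header = b"".join([
        _edf_ascii("0", 8),
        _edf_ascii("X X X X", 80),
        _edf_ascii("Startdate X X X X", 80),
        _edf_ascii("01.01.00", 8),
        _edf_ascii("00.00.00", 8),
        _edf_ascii(256 * (1 + nch), 8),
        _edf_ascii("", 44),
        _edf_ascii(n_records, 8),
        _edf_ascii(1, 8),
        _edf_ascii(nch, 4),
    ])
    fields = [
        [(name or f"ch{i}") for i, name in enumerate(rec.channel_names)],  # label
        [""] * nch,  # transducer
        ["uV"] * nch,
        [f"{v:.8g}"[:8] for v in pmin],
        [f"{v:.8g}"[:8] for v in pmax],
        [str(dmin)] * nch,
        [str(dmax)] * nch,
        [""] * nch,
        [str(fs)] * nch,
        [""] * nch,  # reserved
    ]
    widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
    sig_header = b"".join(
        b"".join(_edf_ascii(v, w) for v in vals) for vals, w in zip(fields, widths)
    )

    scale = (dmax - dmin) / (pmax - pmin)
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_records):
            chunk = padded[:, r * fs : (r + 1) * fs]
            dig = np.rint((chunk - pmin[:, None]) * scale[:, None] + dmin)
            dig = np.clip(dig, dmin, dmax).astype("<i2")
            fh.write(dig.tobytes())


# ---------------------------------------------------------------------------
# Stage / mask TSV
# ---------------------------------------------------------------------------

def read_stages_tsv(path: str | Path, epoch_len: float = 30.0) -> StageAnnotation:
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("epoch_index")
    return StageAnnotation(stages=df["stage"].to_numpy(), epoch_len=epoch_len)


def write_stages_tsv(annot: StageAnnotation, path: str | Path) -> None:
    pd.DataFrame(
        {"epoch_index": np.arange(annot.n_epochs), "stage": annot.stages}
    ).to_csv(path, sep="\t", index=False)


def write_mask_tsv(annot: StageAnnotation, channel_names: list[str], path: str | Path) -> None:
    if annot.mask is None:
        raise ValueError("annotation has no mask")
    e, c = np.nonzero(np.ones_like(annot.mask, dtype=bool))
    pd.DataFrame(
        {
            "epoch_index": e,
            "channel": [channel_names[i] for i in c],
            "status": [_MASK_LABELS[v] for v in annot.mask[e, c]],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess(
    rec: Recording,
    mastoid_labels: tuple[str, str] | None = None,
    *,
    assume_referenced: bool = False,
    target_fs: float = 200.0,
    band: tuple[float, float] = (0.3, 35.0),
) -> Recording:
    """Linked-mastoid re-reference, resample to 200 Hz, bandpass 0.3–35 Hz.

    The bandpass is a zero-phase FIR so slow-oscillation morphology (and the
    slope metrics derived from it) is not phase-distorted.
    """
    data = rec.data
    names = list(rec.channel_names)
    positions = rec.channel_positions
    ref = rec.reference_label

    if mastoid_labels is not None:
        idx = [rec.channel_index(m) for m in mastoid_labels]
        mastoid_mean = data[idx].mean(axis=0)
        keep = [i for i in range(rec.n_channels) if i not in idx]
        data = data[keep] - mastoid_mean
        names = [names[i] for i in keep]
        if positions is not None:
            positions = positions[keep]
        ref = "linked-mastoid"
    elif not assume_referenced:
        raise ValueError(
            "mastoid_labels required unless assume_referenced=True"
        )

    if abs(rec.fs - target_fs) > 1e-9:
        frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator, axis=-1)

    data = bandpass(data, target_fs, band[0], band[1])
    return Recording(
        data=data,
        fs=target_fs,
        channel_names=names,
        channel_positions=positions,
        reference_label=ref,
    )


# ---------------------------------------------------------------------------
# Hjorth parameters
# ---------------------------------------------------------------------------

def _hjorth_arrays(epochs: np.ndarray) -> np.ndarray:
    """Hjorth activity/mobility/complexity along the last axis.

    The derivative is the plain first difference; for a pure tone at
    frequency f this gives mobility = 2 sin(pi f / fs) ~= 2 pi f / fs. The
    constant scale cancels everywhere the pipeline compares mobilities.
    Returns an array of shape epochs.shape[:-1] + (3,).
    """
    x = np.asarray(epochs, dtype=float)
    d1 = np.diff(x, axis=-1)
    d2 = np.diff(d1, axis=-1)
    var0 = x.var(axis=-1)
    var1 = d1.var(axis=-1)
    var2 = d2.var(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mob = np.sqrt(var1 / var0)
        mob_d = np.sqrt(var2 / var1)
        comp = mob_d / mob
    return np.stack([var0, mob, comp], axis=-1)


def hjorth(signal_epoch: np.ndarray) -> HjorthTriple:
    """Hjorth activity (µV²), mobility, and complexity of one epoch.

    A constant signal has zero activity and undefined (NaN) mobility and
    complexity.
    """
    x = np.asarray(signal_epoch, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("epoch must be 1-D with at least 2 samples")
    a, m, c = _hjorth_arrays(x)
    return HjorthTriple(float(a), float(m), float(c))


# ---------------------------------------------------------------------------
# Spherical-spline interpolation
# ---------------------------------------------------------------------------

_SPLINE_M = 4
_SPLINE_TERMS = 20


def _gfun(cosang: np.ndarray) -> np.ndarray:
    """Spherical-spline kernel g(cos gamma) as a truncated Legendre series."""
    n = np.arange(1, _SPLINE_TERMS + 1)
    coefs = np.zeros(_SPLINE_TERMS + 1)
    coefs[1:] = (2 * n + 1) / (n * (n + 1.0)) ** _SPLINE_M
    return npleg.legval(np.clip(cosang, -1.0, 1.0), coefs) / (4 * np.pi)


def _spline_fit(good_pos: np.ndarray, bad_pos: np.ndarray, good_data: np.ndarray) -> np.ndarray:
    """Estimate signals at ``bad_pos`` from ``good_data`` at ``good_pos``."""
    k = good_pos.shape[0]
    if k < 4:
        raise ValueError("need at least 4 good channels with positions")
    g = _gfun(good_pos @ good_pos.T)
    g.flat[:: k + 1] += 1e-8  # ridge for numerical stability
    a = np.zeros((k + 1, k + 1))
    a[:k, :k] = g
    a[:k, k] = 1.0
    a[k, :k] = 1.0
    rhs = np.vstack([good_data, np.zeros((1, good_data.shape[1]))])
    sol = np.linalg.solve(a, rhs)
    c, c0 = sol[:k], sol[k]
    g_bad = _gfun(bad_pos @ good_pos.T)
    return c0[None, :] + g_bad @ c


def interpolate_spherical_spline(rec: Recording, bad_channels: list[str] | list[int]) -> Recording:
    """Replace ``bad_channels`` by a spherical-spline estimate from the rest."""
    if rec.channel_positions is None:
        raise ValueError("channel positions required for interpolation")
    bad_idx = [
        rec.channel_index(b) if isinstance(b, str) else int(b) for b in bad_channels
    ]
    if not bad_idx:
        return rec.copy()
    good_idx = [i for i in range(rec.n_channels) if i not in bad_idx]
    pos = rec.channel_positions / np.linalg.norm(rec.channel_positions, axis=1, keepdims=True)
    est = _spline_fit(pos[good_idx], pos[bad_idx], rec.data[good_idx])
    out = rec.copy()
    out.data[bad_idx] = est
    return out


# ---------------------------------------------------------------------------
# Three-pass artifact pipeline
# ---------------------------------------------------------------------------

def _epochize(data: np.ndarray, spe: int, n_epochs: int) -> np.ndarray:
    """View (n_channels, samples) as (n_epochs, n_channels, spe)."""
    return data[:, : n_epochs * spe].reshape(data.shape[0], n_epochs, spe).swapaxes(0, 1)


def _flat_or_clipped_fraction(epochs: np.ndarray) -> np.ndarray:
    """Fraction of flat (zero first-difference) or rail-clipped samples."""
    d = np.diff(epochs, axis=-1)
    flat = np.abs(d) < 1e-12
    hi = epochs.max(axis=-1, keepdims=True)
    lo = epochs.min(axis=-1, keepdims=True)
    span = np.maximum(hi - lo, 1e-12)
    clipped = (epochs >= hi - 1e-6 * span) | (epochs <= lo + 1e-6 * span)
    frac_flat = flat.mean(axis=-1)
    frac_clip = clipped.mean(axis=-1)
    # only count clipping when the signal actually has dynamic range
    frac_clip = np.where(span[..., 0] > 1e-9, frac_clip, 0.0)
    return np.maximum(frac_flat, frac_clip)


def _robust_z(values: np.ndarray, axis, keepdims=True):
    """(x - mean) / SD along ``axis`` — plain mean/SD, as the pipeline defines."""
    mu = np.nanmean(values, axis=axis, keepdims=keepdims)
    sd = np.nanstd(values, axis=axis, keepdims=keepdims)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.abs(values - mu) / sd


def artifact_pipeline(
    rec: Recording,
    annot: StageAnnotation,
    cfg: ArtifactConfig | None = None,
) -> tuple[Recording, StageAnnotation]:
    """Run the three-pass artifact pipeline; see the module docstring.

    All statistics are computed within each sleep stage separately. Returns
    the interpolated recording and an annotation whose mask records every
    action (clean / interpolated / dropped).
    """
    cfg = cfg or ArtifactConfig()
    out = rec.copy()
    annot = StageAnnotation(
        stages=annot.stages.copy(), epoch_len=annot.epoch_len,
        mask=None if annot.mask is None else annot.mask.copy(),
    )
    annot.init_mask(rec.n_channels)
    spe = annot.epoch_samples(rec.fs)
    n_epochs = min(annot.n_epochs, rec.n_samples // spe)
    stage_groups = {
        s: np.flatnonzero(annot.stages[:n_epochs] == s)
        for s in pd.unique(annot.stages[:n_epochs])
    }

    # ---- pass 1: bad channels (within-epoch, cross-channel comparison)
    h = _hjorth_arrays(_epochize(out.data, spe, n_epochs))  # (e, c, 3)
    bad_channels: set[int] = set()
    for idx in stage_groups.values():
        if len(idx) == 0:
            continue
        z = _robust_z(h[idx], axis=1)  # across channels within epoch
        flagged = np.nan_to_num(z).max(axis=-1) > cfg.bad_channel_epoch_sd
        frac = flagged.mean(axis=0)
        bad_channels.update(np.flatnonzero(frac > cfg.bad_channel_fraction))
    if len(bad_channels) > cfg.max_bad_channel_fraction * rec.n_channels:
        raise RuntimeError(
            f"{len(bad_channels)}/{rec.n_channels} channels flagged bad; "
            "interpolation would be unreliable"
        )
    if bad_channels:
        out = interpolate_spherical_spline(out, sorted(bad_channels))
        annot.mask[:, sorted(bad_channels)] = INTERPOLATED

    # ---- pass 2: outlier epoch/channel cells vs pooled distribution
    epochs3 = _epochize(out.data, spe, n_epochs)
    h = _hjorth_arrays(epochs3)
    flagged_cells = np.zeros((n_epochs, rec.n_channels), dtype=bool)
    for idx in stage_groups.values():
        if len(idx) < 2:
            continue
        z = _robust_z(h[idx].reshape(-1, 3), axis=0).reshape(len(idx), -1, 3)
        flagged_cells[idx] |= np.nan_to_num(z).max(axis=-1) > cfg.epoch_sd
    flagged_cells |= np.abs(epochs3).max(axis=-1) > cfg.max_abs_amp
    flagged_cells |= _flat_or_clipped_fraction(epochs3) > cfg.flat_clip_fraction

    for e in np.flatnonzero(flagged_cells.any(axis=1)):
        bad = np.flatnonzero(flagged_cells[e])
        good = np.flatnonzero(~flagged_cells[e])
        if len(good) < 4 or rec.channel_positions is None:
            annot.mask[e, :] = DROPPED
            continue
        pos = rec.channel_positions
        pos = pos / np.linalg.norm(pos, axis=1, keepdims=True)
        sl = slice(e * spe, (e + 1) * spe)
        out.data[bad, sl] = _spline_fit(pos[good], pos[bad], out.data[good, sl])
        annot.mask[e, bad] = np.maximum(annot.mask[e, bad], INTERPOLATED)

    # ---- pass 3: within-channel epoch outliers -> drop globally; repeat
    for _ in range(1 + cfg.final_pass_repeats):
        epochs3 = _epochize(out.data, spe, n_epochs)
        h = _hjorth_arrays(epochs3)
        dropped = (annot.mask[:n_epochs] == DROPPED).any(axis=1)
        to_drop = np.zeros(n_epochs, dtype=bool)
        for idx in stage_groups.values():
            live = idx[~dropped[idx]]
            if len(live) < 3:
                continue
            z = _robust_z(h[live], axis=0)  # across epochs within channel
            to_drop[live] |= (np.nan_to_num(z).max(axis=-1) > cfg.per_channel_sd).any(axis=1)
        annot.mask[np.flatnonzero(to_drop), :] = DROPPED

    return out, annot
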