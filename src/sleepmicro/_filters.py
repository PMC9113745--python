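"""Zero-phase FIR filtering helpers shared by the detection modules.

All event-level analyses (SO morphology, spindle zero-crossings, phase
estimation) are phase-sensitive, so every band filter here is a linear-phase
FIR applied forward and backward (``filtfilt``), which leaves event timing
and waveform symmetry intact.
"""

from __future__ import annotations

import numpy as np
from scipy import signal


def _numtaps(fs: float, low_edge: float, n_samples: int) -> int:
    """FIR length: ~3 cycles of the lowest band edge, odd, bounded by data."""
    taps = int(round(3.0 * fs / low_edge))
    taps = min(taps, max(3, (n_samples - 2) // 3))
    if taps % 2 == 0:
        taps += 1
    return max(taps, 11)


def bandpass(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    """Zero-phase FIR bandpass along the last axis.

    Parameters
    ----------
    x : array, (..., n_samples)
    fs : sampling rate in Hz
    lo, hi : band edges in Hz; ``hi`` is clipped just below Nyquist.
    """
    x = np.asarray(x, dtype=float)
    nyq = fs / 2.0
    hi = min(hi, 0.99 * nyq)
    if not 0 < lo < hi:
        raise ValueError(f"invalid band ({lo}, {hi}) at fs={fs}")
    taps = _numtaps(fs, lo, x.shape[-1])
    b = signal.firwin(taps, [lo, hi], pass_zero=False, fs=fs)
    padlen = min(3 * taps, x.shape[-1] - 1)
    return signal.filtfilt(b, [1.0], x, axis=-1, padlen=padlen)


def analytic_phase_deg(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase of the analytic signal, degrees in [0, 360).

    Convention: 0 deg at the positive peak of an oscillation, 180 deg at the
    negative peak, (180, 360) on the rising limb.
    """
    return np.angle(signal.hilbert(x), deg=True) % 360.0


def moving_average(x: np.ndarray, n: int) -> np.ndarray:
    """Centered moving average with edge shrinkage, length preserved."""
    if n <= 1:
        return np.asarray(x, dtype=float)
    kernel = np.ones(n) / n
    num = np.convolve(x, kernel, mode="same")
    norm = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return num / norm
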