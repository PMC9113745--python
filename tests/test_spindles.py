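"""Wavelet spindle detector: thresholds, merging, QC, chirp, and metrics."""

import numpy as np
import pytest

from sleepmicro import spindles, synth
from sleepmicro._filters import bandpass
from sleepmicro.spindles import SpindleDetectorConfig

FS = 200.0


def _burst(freq, dur, amp=30.0, fs=FS):
    """Hann-enveloped sinusoid burst (amplitude = half peak-to-peak)."""
    n = int(dur * fs)
    t = np.arange(n) / fs
    return amp * np.hanning(n) * np.sin(2 * np.pi * freq * t)


def _embed(bursts_at, total=300.0, fs=FS, noise_rms=2.0, seed=0):
    """Place bursts into low-level pink noise; returns (signal, mask)."""
    rng_spec = synth.BackgroundSpec(
        n_channels=1, duration=total, rms=noise_rms, seed=seed
    )
    x = synth.make_background(rng_spec).data[0]
    for t0, w in bursts_at:
        i = int(t0 * fs)
        x[i : i + len(w)] += w
    return x, np.ones(x.size, dtype=bool)


class TestCwtMagnitude:
    def test_target_tone_steady_response(self):
        cfg = SpindleDetectorConfig(center_freq=15.0)
        t = np.arange(0, 30, 1 / FS)
        mag = spindles.cwt_magnitude(np.sin(2 * np.pi * 15 * t), FS, cfg)
        mid = mag[1000:-1000]
        assert mid.std() / mid.mean() < 0.01  # ~constant in steady state

    def test_off_target_tone_rejected(self):
        cfg = SpindleDetectorConfig(center_freq=15.0, wavelet_cycles=7)
        t = np.arange(0, 30, 1 / FS)
        on = spindles.cwt_magnitude(np.sin(2 * np.pi * 15 * t), FS, cfg)[1000:-1000]
        off = spindles.cwt_magnitude(np.sin(2 * np.pi * 5 * t), FS, cfg)[1000:-1000]
        assert off.mean() < 0.10 * on.mean()

    def test_zero_signal_zero_magnitude(self):
        cfg = SpindleDetectorConfig()
        assert np.allclose(spindles.cwt_magnitude(np.zeros(4000), FS, cfg), 0.0)

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            spindles.cwt_magnitude(np.zeros(1000), FS, SpindleDetectorConfig(center_freq=120))


class TestDetect:
    def test_single_burst_detected(self):
        x, mask = _embed([(150.0, _burst(15.0, 1.0))])
        evs = spindles.detect_spindles(x, FS, mask, SpindleDetectorConfig())
        assert len(evs) == 1
        assert evs[0].start <= 150.5 <= evs[0].stop

    def test_merge_within_half_second(self):
        # two bursts, 0.3 s gap, merged span 2.0 s -> one event
        w1, w2 = _burst(15.0, 0.85), _burst(15.0, 0.85)
        x, mask = _embed([(150.0, w1), (151.15, w2)])
        evs = spindles.detect_spindles(x, FS, mask, SpindleDetectorConfig())
        assert len(evs) == 1
        assert evs[0].duration <= 3.0

    def test_merge_refused_when_result_exceeds_3s(self):
        # merged span would be ~3.5 s -> two separate events
        w1, w2 = _burst(15.0, 1.6), _burst(15.0, 1.6)
        x, mask = _embed([(150.0, w1), (151.9, w2)])
        evs = spindles.detect_spindles(x, FS, mask, SpindleDetectorConfig())
        assert len(evs) == 2

    def test_overlong_burst_rejected(self):
        # flat-envelope 3.2 s burst: suprathreshold interval > 3 s -> rejected
        from scipy.signal.windows import tukey

        n = int(3.2 * FS)
        t = np.arange(n) / FS
        w = 30.0 * tukey(n, 0.05) * np.sin(2 * np.pi * 15 * t)
        x, mask = _embed([(150.0, w)])
        evs = spindles.detect_spindles(x, FS, mask, SpindleDetectorConfig())
        assert len(evs) == 0

    def test_amplitude_scale_equivariance(self):
        x, mask = _embed([(50.0, _burst(15.0, 1.0)), (150.0, _burst(15.0, 0.8))])
        cfg = SpindleDetectorConfig()
        e1 = spindles.detect_spindles(x, FS, mask, cfg)
        e2 = spindles.detect_spindles(3.7 * x, FS, mask, cfg)
        assert [(e.start, e.stop) for e in e1] == [(e.start, e.stop) for e in e2]

    def test_threshold_monotonicity(self):
        x, mask = _embed(
            [(30.0 + 10 * k, _burst(15.0, 1.0, amp=10 + 4 * k)) for k in range(8)],
            noise_rms=2.0,
        )
        counts = [
            len(spindles.detect_spindles(
                x, FS, mask, SpindleDetectorConfig(core_thresh=ct)))
            for ct in (3.0, 4.5, 6.0, 9.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            spindles.detect_spindles(
                np.zeros(1000), FS, np.zeros(1000, bool), SpindleDetectorConfig()
            )

    def test_slow_fast_independence(self):
        bg = synth.make_background(
            synth.BackgroundSpec(n_channels=1, duration=600, rms=20.0, seed=31))
        slow = synth.SpindleSpec(center_freq=11.0, density=2.0, amplitude=80.0, chirp=0.0)
        fast = synth.SpindleSpec(center_freq=15.0, density=3.0, amplitude=80.0, chirp=0.0)
        rec, t_slow = synth.inject_spindles(bg, slow, seed=32)
        rec, t_fast = synth.inject_spindles(rec, fast, seed=33)
        mask = np.ones(rec.n_samples, bool)
        n11 = len(spindles.detect_spindles(
            rec.data[0], FS, mask, SpindleDetectorConfig(center_freq=11.0)))
        n15 = len(spindles.detect_spindles(
            rec.data[0], FS, mask, SpindleDetectorConfig(center_freq=15.0)))
        # each detector recovers its own target with < 15% cross-talk
        assert abs(n11 - len(t_slow.spindles)) <= 0.15 * len(t_slow.spindles) + 2
        assert abs(n15 - len(t_fast.spindles)) <= 0.15 * len(t_fast.spindles) + 2


class TestQC:
    def test_clean_sigma_burst_kept(self):
        x, mask = _embed([(150.0, _burst(15.0, 1.0))])
        cfg = SpindleDetectorConfig()
        evs = spindles.detect_spindles(x, FS, mask, cfg)
        assert len(spindles.qc_spindles(evs, x, FS, mask, cfg)) == len(evs) == 1

    def test_broadband_artifact_discarded(self):
        # broadband burst whose relative beta increase dominates: crosses
        # the wavelet threshold but is not sigma-specific
        rng = np.random.default_rng(4)
        raw = rng.standard_normal(401)
        w = 60.0 * np.hanning(400) * np.diff(raw) / np.sqrt(2)
        x, mask = _embed([(150.0, w)])
        cfg = SpindleDetectorConfig()
        evs = spindles.detect_spindles(x, FS, mask, cfg)
        assert len(evs) >= 1  # the artifact does trigger the detector
        assert spindles.qc_spindles(evs, x, FS, mask, cfg) == []

    def test_sigma_dominant_event_kept_despite_delta_rise(self):
        # 2x sigma increase with a smaller delta increase is retained
        w_sig = _burst(15.0, 1.0, amp=30.0)
        w_delta = _burst(2.0, 1.0, amp=12.0)
        x, mask = _embed([(150.0, w_sig), (150.0, w_delta)])
        cfg = SpindleDetectorConfig()
        evs = spindles.detect_spindles(x, FS, mask, cfg)
        assert len(evs) == 1
        assert len(spindles.qc_spindles(evs, x, FS, mask, cfg)) == 1


class TestChirp:
    def test_stationary_tone(self):
        t = np.arange(0, 1.0, 1 / FS)
        c, f, ok = spindles.chirp_from_zero_crossings(np.sin(2 * np.pi * 13 * t), FS)
        assert ok
        assert f == pytest.approx(13.0, abs=0.05)
        assert c == pytest.approx(0.0, abs=0.1)

    def test_linear_sweep_and_time_reversal(self):
        # instantaneous frequency 16 -> 14 Hz: half-implied difference -1
        t = np.arange(0, 1.0, 1 / FS)
        phase = 2 * np.pi * (16 * t - t ** 2)  # f(t) = 16 - 2t
        w = np.sin(phase)
        c, f, ok = spindles.chirp_from_zero_crossings(w, FS)
        assert ok and c == pytest.approx(-1.0, abs=0.15)
        c_rev, _, _ = spindles.chirp_from_zero_crossings(w[::-1], FS)
        assert c_rev == pytest.approx(-c, abs=1e-9)

    def test_too_few_crossings_flagged(self):
        t = np.arange(0, 1.0, 1 / FS)
        _, _, ok = spindles.chirp_from_zero_crossings(np.sin(2 * np.pi * 1 * t), FS)
        assert not ok


class TestMetrics:
    def test_density_arithmetic(self):
        from sleepmicro.events import SpindleEvent

        evs = [
            SpindleEvent(channel="c", start=i, stop=i + 1, peak_time=i + 0.5)
            for i in range(30)
        ]
        m = spindles.spindle_metrics(evs, minutes=10.0)
        assert m.density == pytest.approx(3.0)
        assert m.n_events == 30

    def test_zero_events(self):
        m = spindles.spindle_metrics([], minutes=10.0)
        assert m.density == 0.0
        assert np.isnan(m.amplitude)
        with pytest.raises(ValueError):
            spindles.spindle_metrics([], minutes=0.0)

    def test_amplitude_recovery(self):
        x, mask = _embed([(50.0 + 20 * k, _burst(15.0, 1.0, amp=20.0))
                          for k in range(10)])
        cfg = SpindleDetectorConfig()
        evs = spindles.detect_spindles(x, FS, mask, cfg)
        m = spindles.spindle_metrics(evs, 5.0)
        assert m.amplitude == pytest.approx(40.0, rel=0.10)  # 40 µV pk-pk
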