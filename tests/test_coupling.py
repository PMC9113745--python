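"""Coupling: phase convention, ITPC, surrogates, and phase/frequency models."""

import numpy as np
import pytest
from scipy.special import i0, i1

from sleepmicro import coupling as cpl
from sleepmicro import synth
from sleepmicro.coupling import PHASE_BIN_CENTERS, SurrogateConfig
from sleepmicro.events import SOEvent, SpindleEvent

FS = 200.0


class TestSOPhase:
    def test_cosine_convention(self):
        t = np.arange(0, 60, 1 / FS)
        x = 50 * np.cos(2 * np.pi * 1.0 * t)
        phase = cpl.so_phase(x, FS)
        k_max = 10 * int(FS)  # a positive peak away from the edges
        k_min = k_max + int(FS / 2)
        k_rise = k_min + int(FS / 4)  # midpoint of the rising limb
        assert min(phase[k_max], 360 - phase[k_max]) < 1.0
        assert phase[k_min] == pytest.approx(180.0, abs=1.0)
        assert phase[k_rise] == pytest.approx(270.0, abs=5.0)

    def test_phase_increases_within_cycle(self):
        t = np.arange(0, 30, 1 / FS)
        phase = cpl.so_phase(30 * np.cos(2 * np.pi * 0.8 * t), FS)
        d = np.diff(phase[2000:4000]) % 360.0
        assert np.all(d < 180.0)  # monotone modulo wrap


class TestCouplingMetrics:
    def _events_at_phases(self, phases_deg, phase_series_len=100000):
        """Synthetic 1 Hz cosine + spindle peaks at requested phases."""
        t = np.arange(phase_series_len) / FS
        x = 40 * np.cos(2 * np.pi * 1.0 * t)
        phase = cpl.so_phase(x, FS)
        events = []
        for k, target in enumerate(phases_deg):
            # second k+2 has phase = 360*t mod 360; pick sample within cycle
            base = (k + 2) * int(FS)
            offs = int(round((target % 360) / 360 * FS))
            events.append(SpindleEvent(channel="c", start=0, stop=0,
                                       peak_time=(base + offs) / FS))
        return events, phase

    def test_degenerate_clustering(self):
        events, phase = self._events_at_phases([240.0] * 20)
        res = cpl.coupling_metrics(events, [], phase, FS)
        assert res.magnitude_raw == pytest.approx(1.0, abs=1e-3)
        assert res.mean_angle == pytest.approx(240.0, abs=2.0)

    def test_uniform_grid_zero_magnitude(self):
        grid = np.arange(18) * 20.0
        events, phase = self._events_at_phases(grid)
        res = cpl.coupling_metrics(events, [], phase, FS)
        assert res.magnitude_raw < 0.05

    def test_von_mises_bessel_ratio(self):
        rng = np.random.default_rng(0)
        draws = np.degrees(rng.vonmises(np.radians(240.0), 2.0, size=500)) % 360
        events, phase = self._events_at_phases(draws, phase_series_len=150000)
        res = cpl.coupling_metrics(events, [], phase, FS)
        assert res.magnitude_raw == pytest.approx(i1(2.0) / i0(2.0), abs=0.05)

    def test_overlap_counting(self):
        phase = np.zeros(10000)
        sos = [SOEvent("c", 10.0, 11.2, 10.5, -60, 110)]
        sp_in = SpindleEvent("c", start=10.8, stop=11.8, peak_time=11.0)
        sp_out = SpindleEvent("c", start=20.0, stop=21.0, peak_time=20.5)
        res = cpl.coupling_metrics([sp_in, sp_out], sos, phase, FS)
        assert res.overlap_raw == pytest.approx(0.5)

    def test_no_spindles_flagged(self):
        res = cpl.coupling_metrics([], [], np.zeros(100), FS)
        assert res.n_spindles == 0 and np.isnan(res.magnitude_raw)


class TestSurrogates:
    def test_clustered_peaks_high_z(self, so_recording):
        rec, truth = so_recording
        phase = cpl.so_phase(rec.data[0], FS)
        # 100 spindle peaks all at one SO phase
        events = []
        for s in truth.sos[:25]:
            for frac in (0.45, 0.50, 0.55, 0.60):
                pt = s.start + frac * (s.stop - s.start)
                events.append(SpindleEvent("c", pt - 0.4, pt + 0.4, peak_time=pt))
        raw = cpl.coupling_metrics(events, truth.sos, phase, FS)
        res = cpl.surrogate_normalize(
            raw, events, truth.sos, phase, np.ones(rec.n_samples, bool), FS,
            SurrogateConfig(n_shuffles=500, seed=3),
        )
        assert res.magnitude_z > 5
        assert res.subject_p < 0.01

    def test_spindles_inside_sos_high_overlap_z(self, so_recording):
        rec, truth = so_recording
        phase = cpl.so_phase(rec.data[0], FS)
        events = [
            SpindleEvent("c", s.neg_peak_time - 0.3, s.neg_peak_time + 0.3,
                         peak_time=s.neg_peak_time)
            for s in truth.sos[:30]
        ]
        raw = cpl.coupling_metrics(events, truth.sos, phase, FS)
        res = cpl.surrogate_normalize(
            raw, events, truth.sos, phase, np.ones(rec.n_samples, bool), FS,
            SurrogateConfig(n_shuffles=500, seed=4),
        )
        assert res.overlap_raw == 1.0
        assert res.overlap_z > 3

    def test_determinism(self, so_recording):
        rec, truth = so_recording
        phase = cpl.so_phase(rec.data[0], FS)
        events = [SpindleEvent("c", s.start, s.stop, peak_time=s.neg_peak_time)
                  for s in truth.sos[:20]]
        raw = cpl.coupling_metrics(events, truth.sos, phase, FS)
        args = (raw, events, truth.sos, phase, np.ones(rec.n_samples, bool), FS)
        a = cpl.surrogate_normalize(*args, SurrogateConfig(n_shuffles=200, seed=9))
        b = cpl.surrogate_normalize(*args, SurrogateConfig(n_shuffles=200, seed=9))
        assert a.magnitude_z == b.magnitude_z and a.overlap_z == b.overlap_z


class TestInstantaneousFrequency:
    def test_steady_tone(self):
        t = np.arange(0, 30, 1 / FS)
        f = cpl.instantaneous_frequency(np.sin(2 * np.pi * 13 * t), FS, 13.0)
        assert np.abs(f[1000:-1000] - 13.0).max() < 0.05

    def test_linear_sweep_profile(self):
        t = np.arange(0, 30, 1 / FS)
        # 14 -> 16 Hz over 30 s
        phase = 2 * np.pi * (14 * t + t ** 2 / 30)
        f = cpl.instantaneous_frequency(np.sin(phase), FS, 15.0)
        expect = 14 + 2 * t / 30
        assert np.abs(f[2000:-2000] - expect[2000:-2000]).max() < 0.1

    def test_amplitude_modulation_invariance(self):
        t = np.arange(0, 30, 1 / FS)
        env = 1 + 0.8 * np.sin(2 * np.pi * 0.5 * t)
        f = cpl.instantaneous_frequency(env * np.sin(2 * np.pi * 13 * t), FS, 13.0)
        assert np.abs(f[2000:-2000] - 13.0).max() < 0.1


class TestCircularLinear:
    def test_perfect_harmonic(self):
        v = np.cos(np.radians(PHASE_BIN_CENTERS - 110.0))
        assert cpl.circ_linear_corr(PHASE_BIN_CENTERS, v) == pytest.approx(1.0, abs=1e-10)

    def test_constant_values(self):
        assert cpl.circ_linear_corr(PHASE_BIN_CENTERS, np.ones(18)) == 0.0

    def test_agrees_with_reference_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        for _ in range(10):
            v = rng.standard_normal(18)
            ours = cpl.circ_linear_corr(PHASE_BIN_CENTERS, v)
            theirs = pingouin.circ_corrcl(np.radians(PHASE_BIN_CENTERS), v)[0]
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_too_few_bins_raise(self):
        with pytest.raises(ValueError):
            cpl.circ_linear_corr(np.array([10.0, 30.0]), np.array([1.0, 2.0]))


class TestPhaseFreqProfiles:
    def test_injected_chirp_monotone_quintiles(self, so_recording):
        rec, so_truth = so_recording
        out, truth = synth.inject_spindles(
            rec,
            synth.SpindleSpec(density=4.0, chirp=-1.0, coupling_phase=240.0,
                              coupling_kappa=5.0),
            so_truth=so_truth, seed=6,
        )
        phase = cpl.so_phase(out.data[0], FS)
        freq = cpl.instantaneous_frequency(out.data[0], FS, 15.0)
        prof = cpl.phase_freq_profiles(truth.spindles, freq, phase, FS)
        assert np.all(np.diff(prof.freq_by_quintile) < 0)

    def test_cosine_phase_modulation_traced(self):
        # frequency constructed as 13 + cos(phase): bin means follow cosine
        t = np.arange(0, 400, 1 / FS)
        x = 40 * np.cos(2 * np.pi * 1.0 * t)
        phase = cpl.so_phase(x, FS)
        freq = 13.0 + np.cos(np.radians(phase))
        events = [SpindleEvent("c", s, s + 1.0, peak_time=s + 0.5)
                  for s in np.arange(5.0, 390.0, 2.0)]
        prof = cpl.phase_freq_profiles(events, freq, phase, FS)
        expect = 13.0 + np.cos(np.radians(PHASE_BIN_CENTERS))
        assert np.nanmax(np.abs(prof.freq_by_phase_bin - expect)) < 0.1
        assert prof.circ_lin_r > 0.99

    def test_single_event_joint_rows(self):
        phase = np.linspace(0, 359.9, 1000)
        freq = np.full(1000, 12.0)
        ev = [SpindleEvent("c", 0.0, 5.0, peak_time=2.5)]
        prof = cpl.phase_freq_profiles(ev, freq, phase, FS)
        vals = prof.joint[np.isfinite(prof.joint)]
        assert np.allclose(vals, 12.0)


class TestFreqModel:
    def _joint(self, fn):
        q = np.arange(1, 6)[:, None].astype(float)
        th = np.radians(PHASE_BIN_CENTERS)[None, :]
        return fn(q, th)

    def test_pure_progression_cubic(self):
        joint = self._joint(lambda q, th: 15 - 0.2 * q - 0.05 * q ** 3 + 0 * th)
        r2 = cpl.fit_freq_model(joint)
        assert r2["progression"] > 0.999
        assert r2["phase"] < 0.05
        assert r2["combined"] > 0.999

    def test_pure_phase_harmonic(self):
        joint = self._joint(lambda q, th: 13.0 + 0 * q + np.cos(th))
        r2 = cpl.fit_freq_model(joint)
        assert r2["phase"] > 0.999
        assert r2["progression"] < 0.05

    def test_additive_combined_dominates(self):
        rng = np.random.default_rng(2)
        noise = 0.05 * rng.standard_normal((5, 18))
        joint = self._joint(lambda q, th: 15 - 0.3 * q + 0.5 * np.cos(th)) + noise
        r2 = cpl.fit_freq_model(joint)
        assert r2["combined"] >= max(r2["progression"], r2["phase"])

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(3)
        v = rng.standard_normal(18)
        r0 = cpl.circ_linear_corr(PHASE_BIN_CENTERS, v)
        # rotating all phases by a bin shift leaves r unchanged, moves angle
        r1 = cpl.circ_linear_corr((PHASE_BIN_CENTERS + 40.0) % 360.0, v)
        assert r1 == pytest.approx(r0, abs=1e-10)
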