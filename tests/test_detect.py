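"""Ripple/spindle/delta detectors: thresholds, merging, duration rules."""

import numpy as np
import pytest

from sleeplfp.core import NREM, SHORT
from sleeplfp.detect import (
    NoThresholdError,
    detect_delta_waves,
    detect_quiet_wake_ripples,
    detect_ripples,
    detect_spindles,
    ripple_threshold,
    threshold_from_sds,
)
from sleeplfp.preprocess import band_sd, bandpass
from sleeplfp.synth import EventSpec, SimConfig, generate_background, generate_recording


def _tone_burst(fs, t_start, dur_ms, freq=150.0, amp=100.0, total_s=2.0):
    """Constant-amplitude tone burst (near-rectangular envelope)."""
    n = int(total_s * fs)
    x = np.zeros(n)
    i0 = int(t_start * fs)
    nb = int(dur_ms / 1000.0 * fs)
    t = np.arange(nb) / fs
    x[i0 : i0 + nb] = amp * np.sin(2 * np.pi * freq * t)
    return x


class TestThreshold:
    def test_study_day_average_arithmetic(self):
        assert threshold_from_sds([10.0, 12.0], 5.0, 5.0) == 60.0
        assert threshold_from_sds([10.0], 5.0, 5.0) == 55.0

    def test_zero_signal_gives_offset(self):
        assert ripple_threshold([np.zeros(1000)], 100.0, 5.0, 5.0, min_nrem_s=0) == 5.0

    def test_computed_from_segments(self):
        seg1 = np.tile([10.0, -10.0], 500)  # SD exactly 10
        seg2 = np.tile([12.0, -12.0], 500)
        assert ripple_threshold([seg1, seg2], 100.0, 5.0, 5.0, min_nrem_s=0) == 60.0

    def test_short_periods_excluded(self):
        long_seg = np.tile([10.0, -10.0], 20000)  # 400 s at 100 Hz
        short_seg = np.tile([100.0, -100.0], 100)
        thr = ripple_threshold([long_seg, short_seg], 100.0, 5.0, 5.0, min_nrem_s=180.0)
        assert thr == 55.0

    def test_no_qualifying_period_raises(self):
        with pytest.raises(NoThresholdError):
            ripple_threshold([np.zeros(10)], 100.0, min_nrem_s=180.0)


class TestRippleDetector:
    fs = 2500.0

    def test_merge_rule_close_bursts(self):
        # two 30 ms bursts, 15 ms apart: merged under the 20 ms closeness rule
        x = _tone_burst(self.fs, 0.5, 30.0) + _tone_burst(self.fs, 0.545, 30.0)
        events = detect_ripples(x, self.fs, threshold=50.0)
        assert len(events) == 1

    def test_merge_rule_separated_bursts(self):
        x = _tone_burst(self.fs, 0.5, 30.0) + _tone_burst(self.fs, 0.555, 30.0)
        events = detect_ripples(x, self.fs, threshold=50.0)
        assert len(events) == 2

    def test_below_min_duration_rejected(self):
        x = _tone_burst(self.fs, 0.5, 10.0)
        assert detect_ripples(x, self.fs, threshold=50.0) == []

    def test_synthetic_burst_duration_and_class(self):
        fs = 2500.0
        bg = generate_background(60.0, fs, 1.5, 3.0, 42)
        sd = band_sd(bg, fs, (100.0, 300.0))
        spec = EventSpec(
            kind="RIPPLE", center_frequency=150.0, duration_ms=60.0, amplitude=10 * sd
        )
        from sleeplfp.synth import synth_event

        wave, _ = synth_event(spec, fs)
        x = bg.copy()
        x[int(30 * fs) : int(30 * fs) + wave.size] += wave
        filt = bandpass(x, fs, 100.0, 300.0)
        thr = ripple_threshold([filt], fs, 5.0, 5.0, min_nrem_s=0)
        events = detect_ripples(filt, fs, thr)
        assert len(events) == 1
        assert abs(events[0].duration_ms - 60.0) <= 10.0
        assert events[0].length_class == SHORT

    def test_events_in_blanked_intervals_discarded(self):
        x = _tone_burst(self.fs, 0.5, 30.0)
        events = detect_ripples(
            x, self.fs, threshold=50.0, blank_intervals=[(0.4, 0.6)]
        )
        assert events == []

    def test_threshold_monotonicity(self, nrem_recording):
        bundle, _ = nrem_recording
        filt = bandpass(bundle.channel("HPC"), 1000.0, 100.0, 300.0)
        base = ripple_threshold([filt], 1000.0, 5.0, 5.0, min_nrem_s=0)
        counts = [
            len(detect_ripples(filt, 1000.0, base * m)) for m in (0.8, 1.0, 1.5, 2.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_recall_precision_on_ground_truth(self, nrem_recording):
        bundle, gt = nrem_recording
        ripples = [e for e in gt.events if e.kind == "RIPPLE"]
        filt = bandpass(bundle.channel("HPC"), 1000.0, 100.0, 300.0)
        thr = ripple_threshold([filt], 1000.0, 5.0, 5.0, min_nrem_s=0)
        det = detect_ripples(filt, 1000.0, thr)
        hits = sum(any(g.start <= d.peak <= g.end for g in ripples) for d in det)
        assert hits / len(ripples) >= 0.9
        assert hits / len(det) >= 0.9

    def test_emitted_events_satisfy_threshold_predicate(self, nrem_recording):
        from scipy.signal import hilbert

        bundle, _ = nrem_recording
        filt = bandpass(bundle.channel("HPC"), 1000.0, 100.0, 300.0)
        thr = ripple_threshold([filt], 1000.0, 5.0, 5.0, min_nrem_s=0)
        env = np.abs(hilbert(filt))
        for e in detect_ripples(filt, 1000.0, thr):
            seg = env[int(e.start * 1000) : int(e.end * 1000)]
            assert seg.max() >= thr  # crossed the detection threshold
            assert e.start <= e.peak <= e.end

    def test_unfiltered_input_warns(self, rng):
        x = rng.standard_normal(int(120 * 1000))  # broadband
        with pytest.warns(UserWarning, match="band-passed"):
            detect_ripples(x, 1000.0, threshold=50.0, band=(100.0, 300.0))


class TestQuietWakeRipples:
    fs = 1000.0

    def _setup(self, acc_high=False, theta=False):
        n = int(10 * self.fs)
        x = _tone_burst(self.fs, 5.0, 60.0, amp=100.0, total_s=10.0)
        acc = 0.02 * np.random.default_rng(0).standard_normal((3, n))
        if acc_high:
            acc[:, int(4.5 * self.fs) : int(6.0 * self.fs)] += 1.0
        raw = x + 20.0 * np.random.default_rng(1).standard_normal(n)
        if theta:
            # locomotion theta around the candidate only
            t = np.arange(n) / self.fs
            gate = (t > 4.0) & (t < 6.0)
            raw = raw + 200.0 * np.sin(2 * np.pi * 7 * t) * gate
        return x, acc, raw

    def test_still_wake_ripple_detected(self):
        x, acc, raw = self._setup()
        events = detect_quiet_wake_ripples(
            x, self.fs, [(0.0, 10.0)], 50.0, acc=acc, raw=raw,
            nrem_bouts=[(0.0, 2.0)],
        )
        assert len(events) == 1
        assert events[0].context == "QUIET_WAKE"

    def test_movement_vetoes_ripple(self):
        x, acc, raw = self._setup(acc_high=True)
        events = detect_quiet_wake_ripples(
            x, self.fs, [(0.0, 10.0)], 50.0, acc=acc, raw=raw,
            nrem_bouts=[(0.0, 2.0)],
        )
        assert events == []

    def test_locomotion_theta_vetoes_ripple(self):
        x, acc, raw = self._setup(theta=True)
        events = detect_quiet_wake_ripples(
            x, self.fs, [(0.0, 10.0)], 50.0, acc=acc, raw=raw,
            nrem_bouts=[(0.0, 2.0)],
        )
        assert events == []

    def test_missing_accelerometer_warns_but_detects(self):
        x, _, raw = self._setup()
        with pytest.warns(UserWarning, match="accelerometer"):
            events = detect_quiet_wake_ripples(
                x, self.fs, [(0.0, 10.0)], 50.0, acc=None, raw=raw,
                nrem_bouts=[(0.0, 2.0)],
            )
        assert len(events) == 1


class TestSpindleDetector:
    fs = 1000.0

    def _with_burst(self, dur_ms, seed=13):
        bg = generate_background(60.0, self.fs, 1.5, 3.0, seed)
        sd = band_sd(bg, self.fs, (9.0, 20.0))
        from sleeplfp.synth import synth_event

        spec = EventSpec(
            kind="SPINDLE", center_frequency=14.0, duration_ms=dur_ms,
            amplitude=8 * sd,
        )
        wave, _ = synth_event(spec, self.fs)
        x = bg.copy()
        x[int(30 * self.fs) : int(30 * self.fs) + wave.size] += wave
        return bandpass(x, self.fs, 9.0, 20.0)

    def test_single_spindle_duration(self):
        events = detect_spindles(self._with_burst(800.0), self.fs)
        assert len(events) == 1
        assert abs(events[0].duration_ms - 800.0) <= 100.0

    def test_short_burst_rejected(self):
        assert detect_spindles(self._with_burst(200.0), self.fs) == []

    def test_continuous_oscillation_rejected(self):
        t = np.arange(int(10 * self.fs)) / self.fs
        x = 50.0 * np.sin(2 * np.pi * 14 * t)
        assert detect_spindles(x, self.fs) == []


class TestDeltaDetector:
    fs = 1000.0

    def test_single_delta_contains_ground_truth_peak(self):
        cfg = SimConfig(
            duration=60.0,
            fs=self.fs,
            state_schedule=[(NREM, 60.0)],
            event_specs=[EventSpec(kind="DELTA", center_frequency=2.5,
                                   duration_ms=400.0)],
            seed=17,
        )
        bundle, gt = generate_recording(cfg)
        filt = bandpass(bundle.channel("PFC"), self.fs, 1.0, 6.0)
        events = detect_delta_waves(filt, self.fs)
        g = gt.events[0]
        assert any(e.start - 0.02 <= g.peak <= e.end + 0.02 for e in events)

    def test_low_amplitude_wave_rejected(self):
        t = np.arange(int(30 * self.fs)) / self.fs
        x = np.sin(2 * np.pi * 2 * t)  # all peaks at exactly 1.41 SD < 2 SD
        assert detect_delta_waves(x, self.fs) == []

    def test_false_positive_rate_on_white_noise(self, rng):
        rates = []
        for seed in range(10):
            x = bandpass(
                np.random.default_rng(seed).standard_normal(int(60 * self.fs)),
                self.fs, 1.0, 6.0,
            )
            events = detect_delta_waves(x, self.fs, peak_mult=5.0, trough_mult=5.0)
            rates.append(len(events) / 60.0)
        assert np.mean(rates) < 0.05
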