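"""Sequence detection, co-occurrence, and slow-oscillation phase locking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleeplfp.core import DELTA, RIPPLE, SPINDLE, InvalidArgumentError, OscillationEvent
from sleeplfp.coupling import (
    SEQUENCE_WINDOWS_MS,
    cooccurrence,
    detect_d_swr,
    detect_pairs,
    detect_triplets,
    fraction_in_sequences,
    phase_locking_test,
    so_phase_at_events,
)


def _ev(kind, peak, eid, half_dur=0.02):
    return OscillationEvent(
        kind, "HPC" if kind == RIPPLE else "PFC",
        peak - half_dur, peak, peak + half_dur, event_id=eid,
    )


def _interval_ev(kind, start, end, eid):
    return OscillationEvent(
        kind, "HPC" if kind == RIPPLE else "PFC",
        start, (start + end) / 2, end, event_id=eid,
    )


def _random_streams(rng, n_d=50, n_r=50, n_s=50, span=100.0):
    deltas = [_ev(DELTA, p, i) for i, p in enumerate(np.sort(rng.uniform(0, span, n_d)))]
    ripples = [_ev(RIPPLE, p, 1000 + i) for i, p in enumerate(np.sort(rng.uniform(0, span, n_r)))]
    spindles = [_ev(SPINDLE, p, 2000 + i) for i, p in enumerate(np.sort(rng.uniform(0, span, n_s)))]
    return deltas, ripples, spindles


def _brute_pairs(lead, trail, lo_ms, hi_ms):
    return {
        (a.event_id, b.event_id)
        for a in lead
        for b in trail
        if lo_ms <= (b.peak - a.peak) * 1000.0 <= hi_ms
    }


class TestPairs:
    def test_worked_delta_spindle(self):
        d = _ev(DELTA, 1.0, 0)
        s = _ev(SPINDLE, 1.5, 1)
        recs = detect_pairs([d], [s], SEQUENCE_WINDOWS_MS["D_S"], "D_S")
        assert len(recs) == 1
        assert recs[0].inter_peak_intervals_ms == (pytest.approx(500.0),)

    def test_worked_delta_ripple_inclusive_boundary(self):
        d = _ev(DELTA, 1.0, 0)
        r = _ev(RIPPLE, 1.05, 1)
        recs = detect_pairs([d], [r], SEQUENCE_WINDOWS_MS["D_R"], "D_R")
        assert len(recs) == 1  # lag exactly 50 ms is inside [50, 400]

    def test_matches_brute_force_enumeration(self, rng):
        deltas, ripples, _ = _random_streams(rng, 200, 200, 0)
        fast = detect_pairs(deltas, ripples, (50.0, 400.0), "D_R")
        assert {r.member_ids for r in fast} == _brute_pairs(deltas, ripples, 50, 400)

    def test_invalid_window_rejected(self):
        with pytest.raises(InvalidArgumentError):
            detect_pairs([], [], (400.0, 50.0), "D_R")

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(-100.0, 100.0), st.integers(0, 2**31 - 1))
    def test_time_translation_invariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        deltas, ripples, _ = _random_streams(rng, 20, 20, 0)
        base = {r.member_ids for r in detect_pairs(deltas, ripples, (50.0, 400.0), "D_R")}
        d2 = [_ev(DELTA, e.peak + shift, e.event_id) for e in deltas]
        r2 = [_ev(RIPPLE, e.peak + shift, e.event_id) for e in ripples]
        shifted = {r.member_ids for r in detect_pairs(d2, r2, (50.0, 400.0), "D_R")}
        assert base == shifted


class TestTriplets:
    def test_single_chain(self):
        d, r, s = _ev(DELTA, 1.0, 0), _ev(RIPPLE, 1.2, 1), _ev(SPINDLE, 1.7, 2)
        d_r = detect_pairs([d], [r], SEQUENCE_WINDOWS_MS["D_R"], "D_R")
        r_s = detect_pairs([r], [s], SEQUENCE_WINDOWS_MS["R_S"], "R_S")
        trips = detect_triplets(d_r, r_s)
        assert len(trips) == 1
        assert trips[0].member_ids == (0, 1, 2)

    def test_no_rs_means_no_triplet(self):
        d, r = _ev(DELTA, 1.0, 0), _ev(RIPPLE, 1.2, 1)
        d_r = detect_pairs([d], [r], SEQUENCE_WINDOWS_MS["D_R"], "D_R")
        assert detect_triplets(d_r, []) == []

    def test_matches_brute_force_triple_loop(self, rng):
        deltas, ripples, spindles = _random_streams(rng, 40, 40, 40, span=60.0)
        d_r = detect_pairs(deltas, ripples, (50.0, 400.0), "D_R")
        r_s = detect_pairs(ripples, spindles, (2.0, 1000.0), "R_S")
        fast = {t.member_ids for t in detect_triplets(d_r, r_s)}
        brute = {
            (d.event_id, r.event_id, s.event_id)
            for d in deltas
            for r in ripples
            for s in spindles
            if 50 <= (r.peak - d.peak) * 1000 <= 400
            and 2 <= (s.peak - r.peak) * 1000 <= 1000
        }
        assert fast == brute


class TestCooccurrence:
    def test_ripple_inside_spindle(self):
        r = _interval_ev(RIPPLE, 1.00, 1.05, 0)
        s = _interval_ev(SPINDLE, 0.90, 1.60, 1)
        rws, swr = cooccurrence([r], [s])
        assert len(rws) == 1 and len(swr) == 1

    def test_partial_overlap_counts(self):
        r = _interval_ev(RIPPLE, 0.85, 0.95, 0)
        s = _interval_ev(SPINDLE, 0.90, 1.60, 1)
        rws, _ = cooccurrence([r], [s])
        assert len(rws) == 1  # ripple end inside the spindle

    def test_disjoint_intervals_no_record(self):
        r = _interval_ev(RIPPLE, 0.10, 0.15, 0)
        s = _interval_ev(SPINDLE, 0.90, 1.60, 1)
        assert cooccurrence([r], [s]) == ([], [])

    def test_spindle_hosting_multiple_ripples(self):
        rs = [_interval_ev(RIPPLE, 1.0 + 0.1 * i, 1.05 + 0.1 * i, i) for i in range(3)]
        s = _interval_ev(SPINDLE, 0.9, 1.6, 10)
        rws, swr = cooccurrence(rs, [s])
        assert len(rws) == 3
        assert len(swr) == 1 and set(swr[0].member_ids[1:]) == {0, 1, 2}

    def test_directional_counts_match_brute_force(self, rng):
        ripples = [
            _interval_ev(RIPPLE, p, p + 0.06, i)
            for i, p in enumerate(rng.uniform(0, 60, 80))
        ]
        spindles = [
            _interval_ev(SPINDLE, p, p + 0.8, 1000 + i)
            for i, p in enumerate(rng.uniform(0, 60, 40))
        ]
        rws, swr = cooccurrence(ripples, spindles)

        def overlap(r, s):
            return (
                (s.start <= r.start and r.end <= s.end)
                or (s.start <= r.start <= s.end or s.start <= r.end <= s.end)
                or (r.start <= s.start <= r.end or r.start <= s.end <= r.end)
            )

        brute_r = {r.event_id for r in ripples if any(overlap(r, s) for s in spindles)}
        brute_s = {s.event_id for s in spindles if any(overlap(r, s) for r in ripples)}
        assert {rec.member_ids[0] for rec in rws} == brute_r
        assert {rec.member_ids[0] for rec in swr} == brute_s


class TestDSwR:
    def test_conjunction(self):
        d = _ev(DELTA, 1.0, 0)
        s = _interval_ev(SPINDLE, 1.3, 2.1, 1)
        s.peak = 1.5
        r = _interval_ev(RIPPLE, 1.6, 1.66, 2)
        d_s = detect_pairs([d], [s], SEQUENCE_WINDOWS_MS["D_S"], "D_S")
        _, swr = cooccurrence([r], [s])
        recs = detect_d_swr(d_s, swr)
        assert len(recs) == 1
        assert recs[0].member_ids == (0, 1, 2)

    def test_no_hosted_ripple_no_record(self):
        d = _ev(DELTA, 1.0, 0)
        s = _interval_ev(SPINDLE, 1.3, 2.1, 1)
        s.peak = 1.5
        d_s = detect_pairs([d], [s], SEQUENCE_WINDOWS_MS["D_S"], "D_S")
        assert detect_d_swr(d_s, []) == []

    def test_matches_brute_force_join(self, rng):
        deltas, ripples, _ = _random_streams(rng, 30, 0, 0, span=60.0)
        spindles = [
            _interval_ev(SPINDLE, p, p + 0.8, 2000 + i)
            for i, p in enumerate(rng.uniform(0, 60, 30))
        ]
        for s in spindles:
            s.peak = (s.start + s.end) / 2
        ripples = [
            _interval_ev(RIPPLE, p, p + 0.06, 1000 + i)
            for i, p in enumerate(rng.uniform(0, 60, 30))
        ]
        d_s = detect_pairs(deltas, spindles, (100.0, 1300.0), "D_S")
        _, swr = cooccurrence(ripples, spindles)
        fast = {(r.member_ids[0], r.member_ids[1]) for r in detect_d_swr(d_s, swr)}
        hosts = {rec.member_ids[0] for rec in swr}
        brute = {
            (rec.member_ids[0], rec.member_ids[1])
            for rec in d_s
            if rec.member_ids[1] in hosts
        }
        assert fast == brute


class TestFractions:
    def test_no_records_all_alone(self):
        ripples = [_ev(RIPPLE, float(i), i) for i in range(10)]
        out = fraction_in_sequences(ripples, [])
        assert out["SHORT"]["alone"] == 1.0

    def test_all_coupled_none_alone(self):
        ripples = [_ev(RIPPLE, float(i), i) for i in range(5)]
        deltas = [_ev(DELTA, i - 0.2, 100 + i) for i in range(5)]
        recs = detect_pairs(deltas, ripples, (50.0, 400.0), "D_R")
        out = fraction_in_sequences(ripples, recs)
        assert out["SHORT"]["alone"] == 0.0
        assert out["SHORT"]["in_sequence"] == 1.0

    def test_matches_membership_oracle(self, rng):
        deltas, ripples, spindles = _random_streams(rng, 30, 40, 30, span=60.0)
        d_r = detect_pairs(deltas, ripples, (50.0, 400.0), "D_R")
        r_s = detect_pairs(ripples, spindles, (2.0, 1000.0), "R_S")
        out = fraction_in_sequences(ripples, d_r + r_s)
        coupled = {
            r.event_id
            for r in ripples
            if any(r.event_id in rec.member_ids for rec in d_r + r_s)
        }
        assert out["SHORT"]["in_sequence"] == pytest.approx(len(coupled) / len(ripples))


class TestPhase:
    def test_troughs_map_to_180(self):
        fs = 1000.0
        t = np.arange(int(30 * fs)) / fs
        pfc = 100.0 * np.cos(2 * np.pi * 1.0 * t)
        troughs = [5.5, 10.5, 20.5]  # cos minima
        samples = so_phase_at_events(pfc, fs, troughs)
        for p in samples:
            assert abs(p.phase_deg - 180.0) < 2.0

    def test_peaks_map_to_0(self):
        fs = 1000.0
        t = np.arange(int(30 * fs)) / fs
        pfc = 100.0 * np.cos(2 * np.pi * 1.0 * t)
        samples = so_phase_at_events(pfc, fs, [5.0, 10.0, 20.0])
        for p in samples:
            assert min(p.phase_deg, 360 - p.phase_deg) < 2.0

    def test_high_frequency_component_does_not_shift_phase(self):
        fs = 1000.0
        t = np.arange(int(30 * fs)) / fs
        pfc = 100.0 * np.cos(2 * np.pi * 1.0 * t)
        contaminated = pfc + 50.0 * np.sin(2 * np.pi * 20.0 * t)
        peaks = [4.25, 9.75, 15.5]
        a = so_phase_at_events(pfc, fs, peaks)
        b = so_phase_at_events(contaminated, fs, peaks)
        for pa, pb in zip(a, b):
            diff = abs(pa.phase_deg - pb.phase_deg)
            assert min(diff, 360 - diff) < 2.0

    def test_out_of_range_peaks_excluded(self):
        fs = 1000.0
        pfc = np.cos(2 * np.pi * np.arange(int(5 * fs)) / fs)
        with pytest.warns(UserWarning, match="outside"):
            samples = so_phase_at_events(pfc, fs, [1.0, 99.0])
        assert len(samples) == 1


class TestRayleigh:
    def test_identical_phases_max_concentration(self):
        _, r, p = phase_locking_test(np.full(50, 90.0))
        assert r == pytest.approx(1.0)
        assert p < 1e-4

    def test_uniform_grid_no_locking(self):
        _, r, p = phase_locking_test(np.arange(360.0))
        assert r < 1e-6
        assert p > 0.99

    def test_von_mises_sample_detected(self):
        # Monte-Carlo power oracle: kappa=2, n=200 -> p < 0.01 nearly always
        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            phases = np.degrees(rng.vonmises(0.0, 2.0, 200)) % 360
            _, _, p = phase_locking_test(phases)
            hits += p < 0.01
        assert hits >= 0.95 * n_runs

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidArgumentError):
            phase_locking_test(np.array([10.0, 20.0]))
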