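"""Delta/spindle/ripple sequence detection, co-occurrence, and slow-oscillation
phase locking.

Sequence motifs follow the hippocampal-cortical coupling literature:
Delta-Spindle (D-S), Delta-Ripple (D-R), Ripple-Spindle (R-S),
Delta-Ripple-Spindle (D-R-S), Spindle-with-Ripple (SwR, co-occurrence) and
Delta-Spindle-with-Ripple (D-SwR).  A pair qualifies when the trailing
event's peak follows the leading event's peak by an interval inside the
motif's window (inclusive on both ends):

=====  ================
motif  window (ms)
=====  ================
D-S    100 - 1300
D-R    50 - 400
R-S    2 - 1000
=====  ================

Ripple peaks are referenced to the phase of the 0.5-4 Hz cortical slow
oscillation (Hilbert phase, positive peak = 0°, trough = 180°) and locking
is assessed with the Rayleigh test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.stats import circmean

from .core import NA, InvalidArgumentError, OscillationEvent
from .preprocess import bandpass

__all__ = [
    "CouplingRecord",
    "PhaseSample",
    "SEQUENCE_WINDOWS_MS",
    "assign_event_ids",
    "detect_pairs",
    "detect_triplets",
    "cooccurrence",
    "detect_d_swr",
    "fraction_in_sequences",
    "so_phase_at_events",
    "phase_locking_test",
]

SEQUENCE_WINDOWS_MS = {
    "D_S": (100.0, 1300.0),
    "D_R": (50.0, 400.0),
    "R_S": (2.0, 1000.0),
}

SEQUENCE_TYPES = ("D_S", "D_R", "R_S", "D_R_S", "SwR", "D_SwR")
#: membership in any of these counts a ripple as "in sequence"
RIPPLE_SEQUENCE_TYPES = ("D_R", "D_R_S", "R_S", "SwR", "D_SwR")


@dataclass(frozen=True)
class CouplingRecord:
    sequence_type: str
    member_ids: tuple[int, ...]
    inter_peak_intervals_ms: tuple[float, ...] = ()
    ripple_length_class: str = NA


@dataclass(frozen=True)
class PhaseSample:
    event_id: int
    phase_deg: float

    def __post_init__(self) -> None:
        if not 0 <= self.phase_deg < 360:
            raise InvalidArgumentError("phase must lie in [0, 360)")


def assign_event_ids(*event_lists: Sequence[OscillationEvent]) -> None:
    """Give every event a unique id (in time order across the lists)."""
    allev = sorted(
        (e for lst in event_lists for e in lst), key=lambda e: (e.start, e.kind)
    )
    for i, e in enumerate(allev):
        e.event_id = i


def _ripple_class(*events: OscillationEvent) -> str:
    for e in events:
        if e.length_class != NA:
            return e.length_class
    return NA


def detect_pairs(
    lead: Sequence[OscillationEvent],
    trail: Sequence[OscillationEvent],
    window_ms: tuple[float, float],
    sequence_type: str,
) -> list[CouplingRecord]:
    """All ordered (lead, trail) pairs with peak lag inside ``window_ms``.

    The window is inclusive on both ends.  Every qualifying pair yields a
    record, so one lead may appear in several records.
    """
    lo, hi = window_ms
    if lo > hi:
        raise InvalidArgumentError("window min must not exceed max")
    lead = sorted(lead, key=lambda e: e.peak)
    trail = sorted(trail, key=lambda e: e.peak)
    trail_peaks = np.array([e.peak for e in trail])
    records: list[CouplingRecord] = []
    for a in lead:
        i0 = np.searchsorted(trail_peaks, a.peak + lo / 1000.0, side="left")
        i1 = np.searchsorted(trail_peaks, a.peak + hi / 1000.0, side="right")
        for b in trail[i0:i1]:
            lag_ms = (b.peak - a.peak) * 1000.0
            if lo - 1e-9 <= lag_ms <= hi + 1e-9:
                records.append(
                    CouplingRecord(
                        sequence_type=sequence_type,
                        member_ids=(a.event_id, b.event_id),
                        inter_peak_intervals_ms=(lag_ms,),
                        ripple_length_class=_ripple_class(a, b),
                    )
                )
    return records


def detect_triplets(
    d_r: Sequence[CouplingRecord], r_s: Sequence[CouplingRecord]
) -> list[CouplingRecord]:
    """Delta-Ripple-Spindle chains: ripples led by a delta and trailing a spindle.

    All qualifying (delta, ripple, spindle) combinations are enumerated.
    """
    by_ripple: dict[int, list[CouplingRecord]] = {}
    for rec in r_s:
        by_ripple.setdefault(rec.member_ids[0], []).append(rec)
    out: list[CouplingRecord] = []
    for dr in d_r:
        delta_id, ripple_id = dr.member_ids
        for rs in by_ripple.get(ripple_id, []):
            out.append(
                CouplingRecord(
                    sequence_type="D_R_S",
                    member_ids=(delta_id, ripple_id, rs.member_ids[1]),
                    inter_peak_intervals_ms=dr.inter_peak_intervals_ms
                    + rs.inter_peak_intervals_ms,
                    ripple_length_class=dr.ripple_length_class,
                )
            )
    return out


def _co_occurs(r: OscillationEvent, s: OscillationEvent) -> bool:
    # ripple fully inside the spindle
    if s.start <= r.start and r.end <= s.end:
        return True
    # either event's start or end lies inside the other's interval
    for a, b in ((r, s), (s, r)):
        if b.start <= a.start <= b.end or b.start <= a.end <= b.end:
            return True
    return False


def cooccurrence(
    ripples: Sequence[OscillationEvent], spindles: Sequence[OscillationEvent]
) -> tuple[list[CouplingRecord], list[CouplingRecord]]:
    """Ripple-spindle co-occurrence, counted in both directions.

    Returns ``(ripples_with_spindles, spindles_with_ripples)``: one record
    per ripple that co-occurs with at least one spindle (members = ripple id
    then its host spindle ids), and one record per spindle hosting at least
    one ripple (members = spindle id then its ripple ids) — a spindle may
    host several ripples.
    """
    per_ripple: dict[int, list[int]] = {}
    per_spindle: dict[int, list[int]] = {}
    classes: dict[int, str] = {}
    for r in ripples:
        for s in spindles:
            if _co_occurs(r, s):
                per_ripple.setdefault(r.event_id, []).append(s.event_id)
                per_spindle.setdefault(s.event_id, []).append(r.event_id)
                classes[r.event_id] = r.length_class
    rws = [
        CouplingRecord(
            sequence_type="SwR",
            member_ids=(rid, *sids),
            ripple_length_class=classes[rid],
        )
        for rid, sids in per_ripple.items()
    ]
    swr = [
        CouplingRecord(sequence_type="SwR", member_ids=(sid, *rids))
        for sid, rids in per_spindle.items()
    ]
    return rws, swr


def detect_d_swr(
    d_s: Sequence[CouplingRecord], spindles_with_ripples: Sequence[CouplingRecord]
) -> list[CouplingRecord]:
    """Spindles preceded by a delta wave and co-occurring with >= 1 ripple.

    One record per qualifying (delta, spindle) with all hosted ripple ids
    appended to the members.
    """
    hosts = {rec.member_ids[0]: rec.member_ids[1:] for rec in spindles_with_ripples}
    out: list[CouplingRecord] = []
    for ds in d_s:
        delta_id, spindle_id = ds.member_ids
        if spindle_id in hosts:
            out.append(
                CouplingRecord(
                    sequence_type="D_SwR",
                    member_ids=(delta_id, spindle_id, *hosts[spindle_id]),
                    inter_peak_intervals_ms=ds.inter_peak_intervals_ms,
                )
            )
    return out


def fraction_in_sequences(
    ripples: Sequence[OscillationEvent],
    records: Sequence[CouplingRecord],
) -> dict[str, dict[str, float]]:
    """Per-length-class fractions of ripples alone vs in any sequence.

    A ripple is "in sequence" when its id appears in at least one record of
    a ripple-containing motif (D-R, D-R-S, R-S, SwR, D-SwR).  For each
    class the output carries ``alone`` and ``in_sequence`` (summing to 1)
    and, over the coupled ripples only, the fraction participating in each
    motif (set membership, so multiplicity does not inflate fractions).
    """
    members_by_type: dict[str, set[int]] = {t: set() for t in RIPPLE_SEQUENCE_TYPES}
    for rec in records:
        if rec.sequence_type in members_by_type:
            members_by_type[rec.sequence_type].update(rec.member_ids)
    coupled_any = set().union(*members_by_type.values())

    out: dict[str, dict[str, float]] = {}
    for cls in ("SHORT", "LONG"):
        group = [r for r in ripples if r.length_class == cls]
        if not group:
            out[cls] = {"n": 0, "alone": 1.0, "in_sequence": 0.0}
            continue
        ids = {r.event_id for r in group}
        coupled = ids & coupled_any
        entry: dict[str, float] = {
            "n": len(group),
            "in_sequence": len(coupled) / len(ids),
            "alone": 1.0 - len(coupled) / len(ids),
        }
        for t in RIPPLE_SEQUENCE_TYPES:
            entry[t] = (
                len(ids & members_by_type[t]) / len(coupled) if coupled else 0.0
            )
        out[cls] = entry
    return out


def so_phase_at_events(
    pfc: np.ndarray,
    fs: float,
    event_peaks: Sequence[float],
    event_ids: Sequence[int] | None = None,
    band: tuple[float, float] = (0.5, 4.0),
    order: int = 3,
) -> list[PhaseSample]:
    """Slow-oscillation phase at each event peak.

    The cortical channel is band-passed 0.5-4 Hz (zero phase) and the
    Hilbert phase sampled at each peak time, mapped to [0, 360) with the
    convention positive SO peak = 0°, trough = 180°.  Peaks outside the
    signal are excluded with a warning.
    """
    pfc = np.asarray(pfc, dtype=np.float64)
    filt = bandpass(pfc, fs, band[0], band[1], order=order)
    phase = np.angle(sps.hilbert(filt))
    if event_ids is None:
        event_ids = list(range(len(event_peaks)))
    out: list[PhaseSample] = []
    n_skipped = 0
    for eid, t in zip(event_ids, event_peaks):
        i = int(round(t * fs))
        if not 0 <= i < phase.size:
            n_skipped += 1
            continue
        out.append(PhaseSample(event_id=eid, phase_deg=np.degrees(phase[i]) % 360.0))
    if n_skipped:
        warnings.warn(f"{n_skipped} event peaks outside the signal; excluded")
    return out


def phase_locking_test(
    phases: Sequence[PhaseSample] | np.ndarray,
) -> tuple[float, float, float]:
    """Rayleigh test of circular uniformity on event phases.

    Returns ``(mean_direction_deg, resultant_length, p_value)``.
    """
    if len(phases) and isinstance(phases[0], PhaseSample):
        angles = np.array([p.phase_deg for p in phases])
    else:
        angles = np.asarray(phases, dtype=np.float64)
    if angles.size < 5:
        raise InvalidArgumentError("need at least 5 phase samples")
    rad = np.radians(angles)
    mean_dir = float(np.degrees(circmean(rad)) % 360.0)
    r = float(np.abs(np.exp(1j * rad).mean()))
    from pingouin import circ_rayleigh  # deferred: pingouin import is heavy

    _, pval = circ_rayleigh(rad)
    return mean_dir, r, float(pval)
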