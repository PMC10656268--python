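"""Ripple, spindle and delta-wave detection on band-passed LFP.

Ripples are detected by thresholding the analytic-signal envelope of the
band-passed hippocampal trace: a candidate is a suprathreshold run of at
least the minimum duration, nearby candidates are merged, and event edges
are extended outward to the half-threshold crossings.  The detection
threshold is the per-trial-period SD of concatenated NonREM filtered signal
times a multiplier, averaged over periods, plus a fixed µV offset.

Chronic regime: band 100-300 Hz, 5xSD + 5 µV, min 20 ms, closeness 20 ms.
Acute regime:   band 90-200 Hz, ~5xSD, min 50 ms, closeness 80 ms.

Spindle (9-20 Hz) and delta (1-6 Hz) detectors follow the conventions of
the classic freely-moving-animal toolboxes, with every threshold exposed as
an explicit, tunable default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import (
    DELTA,
    NREM,
    QUIET_WAKE,
    RIPPLE,
    SPINDLE,
    InvalidArgumentError,
    OscillationEvent,
)
from .events import event_mean_frequency
from .preprocess import bandpass

__all__ = [
    "DetectionConfig",
    "CHRONIC_RIPPLE",
    "ACUTE_RIPPLE",
    "NoThresholdError",
    "ripple_threshold",
    "threshold_from_sds",
    "detect_ripples",
    "detect_quiet_wake_ripples",
    "detect_spindles",
    "detect_delta_waves",
]


class NoThresholdError(RuntimeError):
    """No trial period qualified for threshold estimation."""


@dataclass(frozen=True)
class DetectionConfig:
    band: tuple[float, float]
    sd_multiplier: float = 5.0
    offset: float = 5.0  # µV added to the threshold
    min_duration_ms: float = 20.0
    closeness_ms: float = 20.0
    boundary_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.boundary_fraction <= 1:
            raise InvalidArgumentError("boundary_fraction must be in (0, 1]")


CHRONIC_RIPPLE = DetectionConfig(band=(100.0, 300.0))
ACUTE_RIPPLE = DetectionConfig(
    band=(90.0, 200.0),
    offset=0.0,
    min_duration_ms=50.0,
    closeness_ms=80.0,
)


def threshold_from_sds(
    period_sds: list[float], sd_multiplier: float = 5.0, offset: float = 5.0
) -> float:
    """Study-day threshold: mean over periods of (multiplier·SD), plus offset."""
    if not period_sds:
        raise NoThresholdError("no qualifying trial periods")
    return float(np.mean([sd_multiplier * s for s in period_sds]) + offset)


def ripple_threshold(
    nrem_bouts_filtered: list[np.ndarray],
    fs: float,
    sd_multiplier: float = 5.0,
    offset: float = 5.0,
    min_nrem_s: float = 180.0,
) -> float:
    """Detection threshold from per-trial-period filtered NonREM signal.

    Each entry of ``nrem_bouts_filtered`` is the concatenated band-passed
    NonREM signal of one trial period; periods contributing no more than
    ``min_nrem_s`` seconds are excluded (paper: periods with more than 3 min
    of NonREM).
    """
    sds = [
        float(np.std(seg))
        for seg in nrem_bouts_filtered
        if seg.size > min_nrem_s * fs
    ]
    return threshold_from_sds(sds, sd_multiplier, offset)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True."""
    if not mask.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(edges[::2], edges[1::2]))


def _merge_close(
    runs: list[tuple[int, int]], max_gap: int
) -> list[tuple[int, int]]:
    """Merge runs whose gap is strictly below ``max_gap`` samples."""
    if not runs:
        return []
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _extend_to_fraction(
    env: np.ndarray, start: int, stop: int, level: float
) -> tuple[int, int]:
    """Grow [start, stop) outward to the nearest crossings of ``level``."""
    s = start
    while s > 0 and env[s - 1] > level:
        s -= 1
    e = stop
    while e < env.size and env[e] > level:
        e += 1
    return s, e


def detect_ripples(
    filtered: np.ndarray,
    fs: float,
    threshold: float,
    min_duration_ms: float = 20.0,
    closeness_ms: float = 20.0,
    boundary_fraction: float = 0.5,
    context: str = NREM,
    blank_intervals: list[tuple[float, float]] | None = None,
    band: tuple[float, float] | None = None,
    channel_role: str = "HPC",
) -> list[OscillationEvent]:
    """Envelope-threshold ripple detection on an already band-passed trace.

    Candidates are envelope runs above ``threshold`` lasting at least
    ``min_duration_ms``; candidates closer than ``closeness_ms`` are merged;
    start/end are the crossings of ``boundary_fraction * threshold``; the
    peak is the envelope maximum.  Events whose peak falls inside a blanked
    interval are discarded.  If ``band`` is given, a cheap spectral probe
    warns when the input does not look band-passed.
    """
    filtered = np.asarray(filtered, dtype=np.float64)
    if threshold <= 0:
        raise InvalidArgumentError("threshold must be positive")
    if band is not None and filtered.size > 512:
        probe = filtered[: min(filtered.size, int(60 * fs))]
        f, p = sps.welch(probe, fs=fs, nperseg=min(probe.size, 4096))
        in_band = p[(f >= band[0]) & (f <= band[1])].sum()
        if in_band < 0.5 * p.sum():
            warnings.warn(
                "input does not look band-passed in the detection band; "
                "detection proceeds"
            )
    env = np.abs(sps.hilbert(filtered))
    runs = [
        r
        for r in _runs(env > threshold)
        if (r[1] - r[0]) / fs * 1000.0 >= min_duration_ms
    ]
    runs = _merge_close(runs, max_gap=int(round(closeness_ms / 1000.0 * fs)))
    level = boundary_fraction * threshold
    extended = [_extend_to_fraction(env, s, e, level) for s, e in runs]
    # boundary extension can make neighbours touch; union overlapping spans
    extended = _merge_close(extended, max_gap=1)

    events: list[OscillationEvent] = []
    for s, e in extended:
        peak_i = s + int(np.argmax(env[s:e]))
        peak_t = peak_i / fs
        if blank_intervals and any(a <= peak_t < b for a, b in blank_intervals):
            continue
        trace = filtered[s:e]
        events.append(
            OscillationEvent(
                kind=RIPPLE,
                channel_role=channel_role,
                start=s / fs,
                peak=peak_t,
                end=e / fs,
                amplitude=float(env[s:e].max()),
                mean_frequency=event_mean_frequency(trace, fs),
                context=context,
            )
        )
    return events


def detect_quiet_wake_ripples(
    filtered: np.ndarray,
    fs: float,
    wake_bouts: list[tuple[float, float]],
    threshold: float,
    acc: np.ndarray | None = None,
    raw: np.ndarray | None = None,
    nrem_bouts: list[tuple[float, float]] | None = None,
    sleep_bouts: list[tuple[float, float]] | None = None,
    min_duration_ms: float = 20.0,
    closeness_ms: float = 20.0,
    boundary_fraction: float = 0.5,
    veto_window_s: float = 0.5,
    acc_sd_mult: float = 2.0,
    theta_mult: float = 2.0,
) -> list[OscillationEvent]:
    """Ripple detection restricted to immobile (quiet) wakefulness.

    Detection is as :func:`detect_ripples` but limited to wake bouts, and a
    candidate is vetoed when, within ``veto_window_s`` of its peak,

    * the accelerometer resultant exceeds its movement threshold
      (mean + ``acc_sd_mult``·SD of the sleep-period resultant), or
    * 5-10 Hz theta power of the raw trace exceeds ``theta_mult`` times its
      NonREM median (locomotion theta).

    Missing accelerometer channels downgrade the movement veto to a warning.
    """
    filtered = np.asarray(filtered, dtype=np.float64)
    mask = np.zeros(filtered.size, dtype=bool)
    for s, e in wake_bouts:
        mask[int(s * fs) : int(e * fs)] = True
    gated = np.where(mask, filtered, 0.0)
    candidates = detect_ripples(
        gated,
        fs,
        threshold,
        min_duration_ms,
        closeness_ms,
        boundary_fraction,
        context=QUIET_WAKE,
    )

    acc_res = acc_thr = None
    if acc is None:
        warnings.warn("no accelerometer channels; movement veto disabled")
    else:
        acc = np.atleast_2d(np.asarray(acc, dtype=np.float64))
        acc_res = np.sqrt((acc**2).sum(axis=0))
        # smooth: movement is sustained, single-sample excursions are noise
        win = max(1, int(veto_window_s * fs))
        acc_res = np.convolve(acc_res, np.ones(win) / win, mode="same")
        ref = sleep_bouts if sleep_bouts else nrem_bouts
        if ref:
            idx = np.concatenate(
                [np.arange(int(s * fs), int(e * fs)) for s, e in ref]
            )
            base = acc_res[idx]
        else:
            base = acc_res
        acc_thr = float(base.mean() + acc_sd_mult * base.std())

    theta_power = theta_thr = None
    if raw is not None:
        theta = bandpass(raw, fs, 5.0, 10.0)
        win = max(1, int(veto_window_s * fs))
        theta_power = np.convolve(theta**2, np.ones(win) / win, mode="same")
        if nrem_bouts:
            idx = np.concatenate(
                [np.arange(int(s * fs), int(e * fs)) for s, e in nrem_bouts]
            )
            theta_thr = theta_mult * float(np.median(theta_power[idx]))
        if not nrem_bouts or theta_thr <= 0:
            theta_thr = theta_mult * float(np.median(theta_power))
        # degenerate reference (numerically zero background): no veto level
        if theta_thr <= 1e-9 * float(theta_power.max() or 1.0):
            theta_power = theta_thr = None

    out: list[OscillationEvent] = []
    nwin = int(veto_window_s * fs)
    for ev in candidates:
        i0 = max(0, int(ev.peak * fs) - nwin)
        i1 = min(filtered.size, int(ev.peak * fs) + nwin)
        if acc_res is not None and acc_res[i0:i1].max() > acc_thr:
            continue
        if theta_power is not None and theta_power[i0:i1].max() > theta_thr:
            continue
        out.append(ev)
    return out


def detect_spindles(
    filtered_9_20: np.ndarray,
    fs: float,
    low_mult: float = 2.5,
    high_mult: float = 5.0,
    min_duration_s: float = 0.4,
    max_duration_s: float = 3.0,
    merge_gap_ms: float = 100.0,
    smooth_ms: float = 100.0,
    channel_role: str = "PFC",
    context: str = NREM,
) -> list[OscillationEvent]:
    """Spindle detection on the 9-20 Hz band-passed cortical trace.

    The analytic-signal envelope, smoothed over ``smooth_ms``, must exceed a
    low threshold (envelope median + ``low_mult``·scaled-MAD) for 0.4-3.0 s
    and a high threshold (median + ``high_mult``·scaled-MAD) at least once;
    start/end sit at the low-threshold crossings; candidates closer than
    ``merge_gap_ms`` merge.  Robust center/scale keeps the thresholds
    insensitive to the spindles themselves.
    """
    x = np.asarray(filtered_9_20, dtype=np.float64)
    env = np.abs(sps.hilbert(x))
    win = max(1, int(round(smooth_ms / 1000.0 * fs)))
    env = np.convolve(env, np.ones(win) / win, mode="same")
    center = float(np.median(env))
    scale = 1.4826 * float(np.median(np.abs(env - center)))
    low = center + low_mult * scale
    high = center + high_mult * scale
    runs = _merge_close(
        _runs(env > low), max_gap=int(round(merge_gap_ms / 1000.0 * fs))
    )
    events: list[OscillationEvent] = []
    for s, e in runs:
        dur = (e - s) / fs
        if not min_duration_s <= dur <= max_duration_s:
            continue
        if env[s:e].max() < high:
            continue
        peak_i = s + int(np.argmax(env[s:e]))
        events.append(
            OscillationEvent(
                kind=SPINDLE,
                channel_role=channel_role,
                start=s / fs,
                peak=peak_i / fs,
                end=e / fs,
                amplitude=float(np.abs(sps.hilbert(x[s:e])).max()),
                mean_frequency=event_mean_frequency(x[s:e], fs),
                context=context,
            )
        )
    return events


def detect_delta_waves(
    filtered_1_6: np.ndarray,
    fs: float,
    peak_mult: float = 2.0,
    trough_mult: float = 1.5,
    min_duration_ms: float = 100.0,
    max_duration_ms: float = 1000.0,
    channel_role: str = "PFC",
    context: str = NREM,
) -> list[OscillationEvent]:
    """Delta-wave detection on the 1-6 Hz band-passed cortical trace.

    A candidate is the segment between an upward and the next downward
    zero-crossing whose positive peak exceeds ``peak_mult``·SD and is
    followed, before the next upward crossing, by a trough below
    ``-trough_mult``·SD; the zero-crossing span must last
    ``min_duration_ms``-``max_duration_ms``.
    """
    x = np.asarray(filtered_1_6, dtype=np.float64)
    sd = float(x.std())
    if sd == 0:
        return []
    sign = x >= 0
    up = np.flatnonzero(~sign[:-1] & sign[1:]) + 1
    down = np.flatnonzero(sign[:-1] & ~sign[1:]) + 1
    events: list[OscillationEvent] = []
    for u in up:
        d_candidates = down[down > u]
        if d_candidates.size == 0:
            break
        d = d_candidates[0]
        dur_ms = (d - u) / fs * 1000.0
        if not min_duration_ms <= dur_ms <= max_duration_ms:
            continue
        seg = x[u:d]
        if seg.max() <= peak_mult * sd:
            continue
        next_up = up[up > d]
        trough_end = next_up[0] if next_up.size else x.size
        if x[d:trough_end].size == 0 or x[d:trough_end].min() >= -trough_mult * sd:
            continue
        peak_i = u + int(np.argmax(seg))
        events.append(
            OscillationEvent(
                kind=DELTA,
                channel_role=channel_role,
                start=u / fs,
                peak=peak_i / fs,
                end=d / fs,
                amplitude=float(seg.max()),
                mean_frequency=event_mean_frequency(x[u:d], fs),
                context=context,
            )
        )
    return events
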