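"""Per-event characteristics and session-level count bookkeeping.

Event amplitude is the peak of the Hilbert envelope of the band-passed
trace; mean frequency is the first spectral moment of its power spectral
density.  Session bookkeeping assigns events to trial-period bins by peak
time, normalizes counts by their per-kind average (so time courses of
frequent and rare event types are comparable), and converts counts to rates
per NonREM minute.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import NREM, Hypnogram, InvalidArgumentError, OscillationEvent

__all__ = [
    "event_amplitude",
    "event_mean_frequency",
    "standard_sleep_bins",
    "bin_and_normalize",
]


def event_amplitude(filtered_trace: np.ndarray) -> float:
    """Maximum of the analytic-signal magnitude of the filtered event trace."""
    trace = np.asarray(filtered_trace, dtype=np.float64)
    if trace.size == 0:
        raise InvalidArgumentError("empty trace")
    return float(np.abs(sps.hilbert(trace)).max())


def event_mean_frequency(filtered_trace: np.ndarray, fs: float) -> float:
    """Power-weighted mean frequency (first spectral moment / zeroth moment).

    Returns NaN for a zero-power trace.
    """
    trace = np.asarray(filtered_trace, dtype=np.float64)
    if trace.size < 2:
        return float("nan")
    freqs, psd = sps.periodogram(trace, fs=fs)
    total = psd.sum()
    if total <= 0:
        return float("nan")
    return float((freqs * psd).sum() / total)


def standard_sleep_bins(
    rest_starts: Sequence[float] | None = None,
    post_start: float | None = None,
    bin_width: float = 2700.0,
    t0: float = 0.0,
) -> list[tuple[int, float, float]]:
    """The study-day bin layout: 8 bins of 45 min.

    Bins 1-4 are the four inter-trial rest periods (starting at
    ``rest_starts``); bins 5-8 divide the 3 h post-trial rest (starting at
    ``post_start``).  Without explicit starts, eight contiguous bins from
    ``t0`` are returned.
    """
    if rest_starts is None:
        rest_starts = [t0 + i * bin_width for i in range(4)]
    if post_start is None:
        post_start = rest_starts[-1] + bin_width
    bins = [(i + 1, float(s), float(s) + bin_width) for i, s in enumerate(rest_starts)]
    bins += [
        (5 + j, post_start + j * bin_width, post_start + (j + 1) * bin_width)
        for j in range(4)
    ]
    return bins


def bin_and_normalize(
    events: Sequence[OscillationEvent],
    period_schedule: Sequence[tuple[int, float, float]],
    hyp: Hypnogram | None = None,
    nrem_state: str = NREM,
) -> pd.DataFrame:
    """Per-bin event counts, average-normalized counts, and NonREM rates.

    Events are assigned to the half-open bin ``[start, end)`` containing
    their peak; events outside every bin are excluded with a warning.
    ``normalized`` divides each kind's counts by that kind's mean count over
    the bins (all zero -> zeros, flagged via the ``all_zero`` column);
    ``rate_per_nrem_min`` divides by the minutes of ``nrem_state`` in the
    bin when a hypnogram is supplied.
    """
    kinds = sorted({e.kind for e in events})
    counts: dict[str, dict[int, int]] = {k: {b: 0 for b, _, _ in period_schedule} for k in kinds}
    n_outside = 0
    for e in events:
        for b, s, t in period_schedule:
            if s <= e.peak < t:
                counts[e.kind][b] += 1
                break
        else:
            n_outside += 1
    if n_outside:
        warnings.warn(f"{n_outside} events outside the period schedule; excluded")

    nrem_minutes: dict[int, float] = {}
    if hyp is not None:
        ivs = hyp.intervals(nrem_state)
        for b, s, t in period_schedule:
            overlap = sum(max(0.0, min(t, e2) - max(s, s2)) for s2, e2 in ivs)
            nrem_minutes[b] = overlap / 60.0

    rows = []
    for kind in kinds:
        vals = np.array([counts[kind][b] for b, _, _ in period_schedule], dtype=float)
        mean = vals.mean()
        all_zero = mean == 0
        norm = vals / mean if not all_zero else np.zeros_like(vals)
        for (b, s, t), c, nv in zip(period_schedule, vals, norm):
            mins = nrem_minutes.get(b)
            rows.append(
                {
                    "kind": kind,
                    "bin": b,
                    "count": int(c),
                    "normalized": float(nv),
                    "rate_per_nrem_min": (
                        float(c / mins) if mins else float("nan")
                    ),
                    "all_zero": bool(all_zero),
                }
            )
    return pd.DataFrame(rows)
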