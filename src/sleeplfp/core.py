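"""Core domain types shared across the pipeline, plus on-disk formats.

Conventions used throughout the package:

* times are seconds from recording start; intervals are half-open
  ``[start, end)`` unless a rule explicitly says otherwise,
* voltages are microvolts (µV),
* channel roles are ``HPC`` (hippocampal CA1), ``PFC`` (prelimbic cortex)
  and three accelerometer axes ``ACC_X/Y/Z``.

A recording travels as a :class:`SignalBundle`; per-epoch sleep labels as a
:class:`Hypnogram`; detected oscillations as :class:`OscillationEvent`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# states and event kinds

WAKE = "WAKE"
NREM = "NREM"
INTERMEDIATE = "INTERMEDIATE"
REM = "REM"
NREM_LIKE = "NREM_LIKE"
REM_LIKE = "REM_LIKE"
ARTIFACT = "ARTIFACT"

SLEEP_STATES = (NREM, INTERMEDIATE, REM)
CHRONIC_STATES = (WAKE, NREM, INTERMEDIATE, REM)
ACUTE_STATES = (NREM_LIKE, REM_LIKE, ARTIFACT)

QUIET_WAKE = "QUIET_WAKE"

RIPPLE = "RIPPLE"
SPINDLE = "SPINDLE"
DELTA = "DELTA"

SHORT = "SHORT"
LONG = "LONG"
NA = "NA"

#: ripples strictly longer than this are LONG, at or below it SHORT
LONG_RIPPLE_BOUNDARY_MS = 100.0


class InvalidArgumentError(ValueError):
    """Raised when an operation receives arguments violating its contract."""


@dataclass
class SignalBundle:
    """Multi-channel continuous recording.

    ``samples`` is ``(n_channels, n_samples)`` float64 µV; ``channel_roles``
    names each row.
    """

    samples: np.ndarray
    fs: float
    channel_roles: list[str]
    units: str = "uV"
    session_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.fs <= 0:
            raise InvalidArgumentError("fs must be positive")
        if self.samples.shape[0] != len(self.channel_roles):
            raise InvalidArgumentError(
                "channel_roles length must match number of channels"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, role: str) -> np.ndarray:
        try:
            idx = self.channel_roles.index(role)
        except ValueError as exc:
            raise KeyError(f"no channel with role {role!r}") from exc
        return self.samples[idx]

    def has_channel(self, role: str) -> bool:
        return role in self.channel_roles

    # -- flat-binary + JSON sidecar interchange format ------------------

    def save(self, path: str | Path, scale_uv_per_count: float = 0.195) -> None:
        """Write interleaved little-endian int16 + a JSON sidecar.

        ``scale_uv_per_count`` maps integer counts to µV (default matches
        common headstage gain).
        """
        path = Path(path)
        counts = np.round(self.samples / scale_uv_per_count)
        counts = np.clip(counts, -32768, 32767).astype("<i2")
        counts.T.reshape(-1).tofile(path)
        sidecar = {
            "fs": self.fs,
            "n_channels": self.samples.shape[0],
            "channel_roles": self.channel_roles,
            "units": self.units,
            "scale_uV_per_count": scale_uv_per_count,
            "session_meta": self.session_meta,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2)
        )

    @classmethod
    def load(cls, path: str | Path) -> "SignalBundle":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        raw = np.fromfile(path, dtype="<i2")
        n_ch = int(sidecar["n_channels"])
        samples = (
            raw.reshape(-1, n_ch).T.astype(np.float64)
            * float(sidecar["scale_uV_per_count"])
        )
        return cls(
            samples=samples,
            fs=float(sidecar["fs"]),
            channel_roles=list(sidecar["channel_roles"]),
            units=sidecar.get("units", "uV"),
            session_meta=sidecar.get("session_meta", {}),
        )


@dataclass
class Hypnogram:
    """Per-epoch sleep-state labels with a fixed epoch duration."""

    states: list[str]
    epoch_s: float

    def __post_init__(self) -> None:
        if self.epoch_s <= 0:
            raise InvalidArgumentError("epoch_s must be positive")
        self.states = list(self.states)

    @property
    def duration(self) -> float:
        return len(self.states) * self.epoch_s

    def state_at(self, t: float) -> str:
        idx = int(t / self.epoch_s)
        if not 0 <= idx < len(self.states):
            raise InvalidArgumentError(f"time {t} outside hypnogram")
        return self.states[idx]

    def intervals(self, state: str) -> list[tuple[float, float]]:
        """Half-open [start, end) intervals of maximal runs of ``state``."""
        out: list[tuple[float, float]] = []
        start = None
        for i, s in enumerate(self.states):
            if s == state and start is None:
                start = i
            elif s != state and start is not None:
                out.append((start * self.epoch_s, i * self.epoch_s))
                start = None
        if start is not None:
            out.append((start * self.epoch_s, len(self.states) * self.epoch_s))
        return out

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"epoch_index": np.arange(len(self.states)), "state": self.states}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, epoch_s: float) -> "Hypnogram":
        df = pd.read_csv(path)
        return cls(states=df["state"].tolist(), epoch_s=epoch_s)


@dataclass
class OscillationEvent:
    """A detected oscillation with its anchor times and characteristics."""

    kind: str
    channel_role: str
    start: float
    peak: float
    end: float
    amplitude: float = np.nan
    mean_frequency: float = np.nan
    context: str = NREM
    event_id: int = -1

    def __post_init__(self) -> None:
        if not (self.start <= self.peak <= self.end):
            raise InvalidArgumentError("event must satisfy start <= peak <= end")

    @property
    def duration_ms(self) -> float:
        return (self.end - self.start) * 1000.0

    @property
    def length_class(self) -> str:
        if self.kind != RIPPLE:
            return NA
        return LONG if self.duration_ms > LONG_RIPPLE_BOUNDARY_MS else SHORT


def events_to_frame(events: Sequence[OscillationEvent]) -> pd.DataFrame:
    """Long-format event table (the CSV interchange shape)."""
    return pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "kind": [e.kind for e in events],
            "context": [e.context for e in events],
            "channel_role": [e.channel_role for e in events],
            "start_s": [e.start for e in events],
            "peak_s": [e.peak for e in events],
            "end_s": [e.end for e in events],
            "duration_ms": [e.duration_ms for e in events],
            "amplitude_uV": [e.amplitude for e in events],
            "mean_freq_hz": [e.mean_frequency for e in events],
            "length_class": [e.length_class for e in events],
        }
    )


def frame_to_events(df: pd.DataFrame) -> list[OscillationEvent]:
    return [
        OscillationEvent(
            kind=row.kind,
            channel_role=row.channel_role,
            start=row.start_s,
            peak=row.peak_s,
            end=row.end_s,
            amplitude=row.amplitude_uV,
            mean_frequency=row.mean_freq_hz,
            context=row.context,
            event_id=int(row.event_id),
        )
        for row in df.itertuples()
    ]


@dataclass
class ArtifactMask:
    """Disjoint, sorted intervals that were blanked out of a signal."""

    intervals: list[tuple[float, float]] = field(default_factory=list)
    replacement_value: float = 0.0

    def __post_init__(self) -> None:
        self.intervals = merge_intervals(self.intervals)

    @property
    def total_duration(self) -> float:
        return sum(e - s for s, e in self.intervals)

    def contains(self, t: float) -> bool:
        return any(s <= t < e for s, e in self.intervals)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.intervals, columns=["start_s", "end_s"]).to_csv(
            path, index=False
        )


def merge_intervals(
    intervals: Sequence[tuple[float, float]],
) -> list[tuple[float, float]]:
    """Union of intervals: sorted and with overlapping/touching ones merged."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]
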