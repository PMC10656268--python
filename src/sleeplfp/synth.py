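"""Ground-truthed synthetic LFP recordings.

The generator produces two-region (hippocampal CA1 + prelimbic cortex)
recordings with a 1/f^chi aperiodic background of known exponent and offset,
state-structured narrow-band components (slow oscillation on PFC during
NonREM-like states, theta on HPC during REM-like states), embedded
oscillation events (ripples, spindles, delta waves), cross-region event
sequences at controlled lags, ripple peaks at controlled slow-oscillation
phases, movement-artifact excursions, and a 3-axis accelerometer whose
variance is elevated only during wake and artifact segments.

Every embedded feature is recorded in a :class:`GroundTruth` so downstream
detectors and statistics can be validated without any real data.

Randomness: one ``numpy`` Generator seeded from ``SimConfig.seed``; draws
happen in a fixed documented order (backgrounds, accelerometer, artifacts,
coupling specs, phase-locked events, free events), so identical configs give
bit-identical recordings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import (
    DELTA,
    NREM,
    NREM_LIKE,
    REM,
    REM_LIKE,
    RIPPLE,
    SPINDLE,
    WAKE,
    Hypnogram,
    InvalidArgumentError,
    SignalBundle,
)

__all__ = [
    "EventSpec",
    "PhaseSpec",
    "ArtifactSpec",
    "SimConfig",
    "GroundTruth",
    "generate_background",
    "synth_event",
    "generate_recording",
]

# which states carry which narrow-band component
_SO_STATES = (NREM, NREM_LIKE)
_THETA_STATES = (REM, REM_LIKE)

#: per-kind (center frequency Hz, duration ms) used when a coupling or phase
#: spec needs an event without an explicit EventSpec
DEFAULT_EVENT_PARAMS = {
    RIPPLE: (150.0, 60.0),
    SPINDLE: (14.0, 800.0),
    DELTA: (2.5, 400.0),
}

DEFAULT_CHANNEL = {RIPPLE: "HPC", SPINDLE: "PFC", DELTA: "PFC"}

_KIND_BANDS = {
    RIPPLE: (90.0, 300.0),  # union of chronic (100-300) and acute (90-200)
    SPINDLE: (9.0, 20.0),
    DELTA: (1.0, 6.0),
}


@dataclass
class EventSpec:
    """One oscillation event to embed.

    ``time`` is the peak time in seconds, or ``None`` for random placement
    within ``state``.  ``amplitude`` is the envelope peak in µV; ``None``
    means 10x the background SD in the event's detection band.
    """

    kind: str
    center_frequency: float | None = None
    duration_ms: float | None = None
    amplitude: float | None = None
    time: float | None = None
    state: str = NREM
    channel_role: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KIND_BANDS:
            raise InvalidArgumentError(f"unknown event kind {self.kind!r}")
        if self.center_frequency is None:
            self.center_frequency = DEFAULT_EVENT_PARAMS[self.kind][0]
        if self.duration_ms is None:
            self.duration_ms = DEFAULT_EVENT_PARAMS[self.kind][1]
        if self.channel_role is None:
            self.channel_role = DEFAULT_CHANNEL[self.kind]
        lo, hi = _KIND_BANDS[self.kind]
        if not lo <= self.center_frequency <= hi:
            raise InvalidArgumentError(
                f"{self.kind} frequency {self.center_frequency} Hz outside "
                f"[{lo}, {hi}] Hz"
            )
        if self.duration_ms <= 0:
            raise InvalidArgumentError("duration must be positive")


@dataclass
class PhaseSpec:
    """Lock ripple peaks to a slow-oscillation phase.

    ``concentration`` is the von Mises kappa of the sampled phases around
    ``target_phase_deg`` (phase convention: SO positive peak = 0deg,
    trough = 180deg).
    """

    so_frequency: float = 1.0
    target_phase_deg: float = 180.0
    concentration: float = 20.0
    so_amplitude: float = 150.0

    def __post_init__(self) -> None:
        if not 0.5 <= self.so_frequency <= 4.0:
            raise InvalidArgumentError("so_frequency must lie in 0.5-4 Hz")
        if not 0.0 <= self.target_phase_deg < 360.0:
            raise InvalidArgumentError("target_phase_deg must lie in [0, 360)")


@dataclass
class ArtifactSpec:
    count: int = 3
    amplitude: float = 2000.0
    duration_s: float = 0.2


@dataclass
class SimConfig:
    duration: float = 60.0
    fs: float = 2500.0
    aperiodic_exponent: float = 1.5
    aperiodic_offset: float = 3.0  # log10(uV^2/Hz) at 1 Hz
    state_schedule: list[tuple[str, float]] = field(
        default_factory=lambda: [(NREM, 60.0)]
    )
    epoch_s: float = 1.0
    event_specs: list[EventSpec] = field(default_factory=list)
    coupling_specs: list[tuple[str, str, float, float, int]] = field(
        default_factory=list
    )  # (lead kind, trail kind, lag ms, jitter ms, count)
    phase_spec: Optional[PhaseSpec] = None
    artifact_spec: Optional[ArtifactSpec] = None
    so_amplitude: float = 150.0  # µV, NonREM slow oscillation on PFC
    theta_amplitude: float = 100.0  # µV, REM theta on HPC
    theta_frequency: float = 7.0  # natural REM theta (6-8 Hz)
    # urethane slows cortical rhythms: anesthesia-like states use these
    so_frequency_acute: float = 0.7
    theta_frequency_acute: float = 4.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.fs <= 0:
            raise InvalidArgumentError("duration and fs must be positive")
        total = sum(d for _, d in self.state_schedule)
        if abs(total - self.duration) > 1e-9:
            raise InvalidArgumentError(
                f"state_schedule durations sum to {total}, expected {self.duration}"
            )


@dataclass
class GTEvent:
    kind: str
    channel_role: str
    start: float
    peak: float
    end: float
    amplitude: float
    frequency: float


@dataclass
class GroundTruth:
    """Exhaustive bookkeeping of everything embedded in a recording."""

    events: list[GTEvent] = field(default_factory=list)
    hypnogram: Hypnogram | None = None
    aperiodic: tuple[float, float] = (0.0, 0.0)  # (offset, exponent)
    coupled_tuples: list[tuple[int, ...]] = field(default_factory=list)
    event_phases: list[tuple[int, float]] = field(default_factory=list)
    artifact_intervals: list[tuple[float, float]] = field(default_factory=list)

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kind": [e.kind for e in self.events],
                "channel_role": [e.channel_role for e in self.events],
                "start_s": [e.start for e in self.events],
                "peak_s": [e.peak for e in self.events],
                "end_s": [e.end for e in self.events],
                "amplitude_uV": [e.amplitude for e in self.events],
                "frequency_hz": [e.frequency for e in self.events],
            }
        )

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.events_frame().to_csv(prefix.with_suffix(".events.csv"), index=False)
        if self.hypnogram is not None:
            self.hypnogram.to_csv(prefix.with_suffix(".hypnogram.csv"))


# ---------------------------------------------------------------------------
# background


def generate_background(
    duration: float,
    fs: float,
    exponent: float,
    offset: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Zero-mean noise whose one-sided PSD is ``10**offset / f**exponent``.

    Synthesized by spectral shaping: each rFFT bin gets an independent
    complex-Gaussian amplitude with expected power matching the target
    density, so a log10-log10 least-squares fit of the periodogram recovers
    slope ``-exponent`` and intercept ``offset`` in expectation.
    """
    if duration <= 0 or fs <= 0:
        raise InvalidArgumentError("duration and fs must be positive")
    n = int(round(duration * fs))
    if n < 2:
        raise InvalidArgumentError("need at least 2 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    target = np.zeros_like(freqs)
    target[1:] = 10.0**offset / freqs[1:] ** exponent  # uV^2/Hz
    # E|X_k|^2 = S(f_k) * fs * n / 2 makes the one-sided periodogram unbiased
    sigma = np.sqrt(target * fs * n / 2.0)
    re = rng.standard_normal(freqs.size)
    im = rng.standard_normal(freqs.size)
    spectrum = sigma * (re + 1j * im) / np.sqrt(2.0)
    spectrum[0] = 0.0
    if n % 2 == 0:
        spectrum[-1] = sigma[-1] * re[-1]
    x = np.fft.irfft(spectrum, n=n)
    return x


# ---------------------------------------------------------------------------
# event waveforms


def _envelope(n: int, shape: str, alpha: float) -> np.ndarray:
    if shape == "tukey":
        return sps.windows.tukey(n, alpha=alpha)
    if shape == "hann":
        return sps.windows.hann(n)
    raise InvalidArgumentError(f"unknown envelope shape {shape!r}")


def synth_event(
    spec: EventSpec,
    fs: float,
    envelope: str = "tukey",
    alpha: float = 0.25,
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Waveform for one event and its (start, peak, end) relative to onset.

    The waveform is a sinusoid at ``spec.center_frequency`` under a smooth
    unimodal envelope peaking at ``spec.amplitude``.  The default envelope is
    a tapered cosine (Tukey) whose flat top keeps the suprathreshold width of
    the event close to its nominal duration; a Hann envelope is available.
    Delta waves start on the positive half-cycle so a full cycle reads
    peak-then-trough, mirroring a cortical down-state signature.
    """
    if spec.center_frequency >= fs / 2:
        raise InvalidArgumentError("event frequency must be below Nyquist")
    if spec.amplitude is None:
        raise InvalidArgumentError("spec.amplitude must be resolved before synthesis")
    n = max(2, int(round(spec.duration_ms / 1000.0 * fs)))
    t = np.arange(n) / fs
    env = _envelope(n, envelope, alpha) * spec.amplitude
    if spec.kind == DELTA:
        carrier = np.sin(2 * np.pi * spec.center_frequency * t)
    else:
        # cosine peaks at the envelope center -> waveform max == envelope max
        carrier = np.cos(2 * np.pi * spec.center_frequency * (t - t[n // 2]))
    wave = env * carrier
    duration = n / fs
    if spec.kind == DELTA:
        peak = t[int(np.argmax(wave))]
    else:
        peak = t[n // 2]
    return wave, (0.0, peak, duration)


# ---------------------------------------------------------------------------
# full recording


def _band_sd(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    lo, hi = band
    hi = min(hi, 0.999 * fs / 2)
    sos = sps.butter(3, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return float(np.std(sps.sosfiltfilt(sos, x)))


def _state_mask(
    intervals: Sequence[tuple[float, float]], n: int, fs: float, ramp_s: float = 0.25
) -> np.ndarray:
    """Soft 0/1 mask with raised-cosine ramps at interval edges."""
    mask = np.zeros(n)
    nr = max(1, int(ramp_s * fs))
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
    for s, e in intervals:
        i0, i1 = int(round(s * fs)), min(n, int(round(e * fs)))
        if i1 <= i0:
            continue
        mask[i0:i1] = 1.0
        if i1 - i0 > 2 * nr:
            mask[i0 : i0 + nr] = np.minimum(mask[i0 : i0 + nr], ramp)
            mask[i1 - nr : i1] = np.minimum(mask[i1 - nr : i1], ramp[::-1])
    return mask


def _hypnogram_from_schedule(
    schedule: Sequence[tuple[str, float]], epoch_s: float
) -> Hypnogram:
    states: list[str] = []
    for state, dur in schedule:
        n_epochs = int(round(dur / epoch_s))
        states.extend([state] * n_epochs)
    return Hypnogram(states=states, epoch_s=epoch_s)


def _place_time(
    rng: np.random.Generator,
    intervals: list[tuple[float, float]],
    half_dur: float,
    occupied: list[tuple[float, float]],
    min_gap: float = 0.3,
    max_tries: int = 200,
) -> float | None:
    """Random peak time inside one of ``intervals`` avoiding ``occupied``."""
    usable = [(s + half_dur, e - half_dur) for s, e in intervals if e - s > 2 * half_dur]
    if not usable:
        return None
    lengths = np.array([e - s for s, e in usable])
    for _ in range(max_tries):
        i = rng.choice(len(usable), p=lengths / lengths.sum())
        t = rng.uniform(*usable[i])
        if all(
            t + half_dur + min_gap <= s or t - half_dur - min_gap >= e
            for s, e in occupied
        ):
            return t
    return None


def generate_recording(config: SimConfig) -> tuple[SignalBundle, GroundTruth]:
    """Generate a five-channel bundle (HPC, PFC, ACC_X/Y/Z) plus ground truth.

    Draw order from the single seeded generator: HPC background, PFC
    background, accelerometer noise, artifact times, coupling-spec events,
    phase-locked ripples, then free events in ``event_specs`` order.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs

    hpc = generate_background(
        config.duration, fs, config.aperiodic_exponent, config.aperiodic_offset, rng
    )
    pfc = generate_background(
        config.duration, fs, config.aperiodic_exponent, config.aperiodic_offset, rng
    )
    acc = 0.02 * rng.standard_normal((3, n))

    hyp = _hypnogram_from_schedule(config.state_schedule, config.epoch_s)
    gt = GroundTruth(
        hypnogram=hyp,
        aperiodic=(config.aperiodic_offset, config.aperiodic_exponent),
    )

    # state-structured narrow-band components (anesthesia-like states use
    # the urethane-slowed frequencies)
    wake_ivs = hyp.intervals(WAKE)
    so_amp = config.phase_spec.so_amplitude if config.phase_spec else config.so_amplitude
    if config.phase_spec is not None:
        # SO present throughout so locked ripples can be placed anywhere
        pfc = pfc + so_amp * np.cos(2 * np.pi * config.phase_spec.so_frequency * t)
    else:
        for state, freq in ((NREM, 1.0), (NREM_LIKE, config.so_frequency_acute)):
            ivs = hyp.intervals(state)
            if ivs:
                pfc = pfc + so_amp * np.cos(2 * np.pi * freq * t) * _state_mask(
                    ivs, n, fs
                )
    for state, freq in (
        (REM, config.theta_frequency),
        (REM_LIKE, config.theta_frequency_acute),
    ):
        ivs = hyp.intervals(state)
        if ivs:
            hpc = hpc + config.theta_amplitude * np.sin(
                2 * np.pi * freq * t
            ) * _state_mask(ivs, n, fs)
    if wake_ivs:
        acc += 0.2 * rng.standard_normal((3, n)) * _state_mask(wake_ivs, n, fs)

    # reference background band SDs for default amplitudes (pre-event signal)
    band_sd_cache: dict[str, float] = {}

    def default_amplitude(kind: str, channel: str) -> float:
        key = f"{kind}:{channel}"
        if key not in band_sd_cache:
            sig = hpc if channel == "HPC" else pfc
            band_sd_cache[key] = _band_sd(sig, fs, _KIND_BANDS[kind])
        return 10.0 * band_sd_cache[key]

    # artifacts
    artifact_mask = np.zeros(n, dtype=bool)
    if config.artifact_spec is not None:
        spec = config.artifact_spec
        for _ in range(spec.count):
            t0 = rng.uniform(0, config.duration - spec.duration_s)
            i0, i1 = int(t0 * fs), int((t0 + spec.duration_s) * fs)
            hpc[i0:i1] += spec.amplitude
            pfc[i0:i1] += spec.amplitude
            acc[:, i0:i1] += 0.2 * rng.standard_normal((3, i1 - i0))
            gt.artifact_intervals.append((t0, t0 + spec.duration_s))
            artifact_mask[i0:i1] = True

    channels = {"HPC": hpc, "PFC": pfc}
    occupied: dict[str, list[tuple[float, float]]] = {}

    def embed(spec: EventSpec, peak_time: float) -> int:
        """Add the event waveform centered at ``peak_time``; return gt index."""
        if spec.amplitude is None:
            spec = replace(
                spec, amplitude=default_amplitude(spec.kind, spec.channel_role)
            )
        wave, (_, peak_rel, dur) = synth_event(spec, fs)
        start = peak_time - peak_rel
        i0 = int(round(start * fs))
        if i0 < 0 or i0 + wave.size > n:
            raise InvalidArgumentError(
                f"event at {peak_time:.3f}s does not fit in the recording"
            )
        key = f"{spec.kind}:{spec.channel_role}"
        for s0, e0 in occupied.get(key, []):
            if start < e0 and start + dur > s0:
                warnings.warn(
                    f"overlapping {spec.kind} events near {peak_time:.3f}s; "
                    "both recorded in ground truth"
                )
        occupied.setdefault(key, []).append((start, start + dur))
        channels[spec.channel_role][i0 : i0 + wave.size] += wave
        gt.events.append(
            GTEvent(
                kind=spec.kind,
                channel_role=spec.channel_role,
                start=start,
                peak=start + peak_rel,
                end=start + dur,
                amplitude=spec.amplitude,
                frequency=spec.center_frequency,
            )
        )
        return len(gt.events) - 1

    def placement_intervals(state: str) -> list[tuple[float, float]]:
        ivs = hyp.intervals(state)
        return ivs if ivs else [(0.0, config.duration)]

    # coupling specs: lead placed randomly in NREM, trail at lead + lag
    for lead_kind, trail_kind, lag_ms, jitter_ms, count in config.coupling_specs:
        for _ in range(count):
            lag = (
                lag_ms + rng.uniform(-jitter_ms, jitter_ms) if jitter_ms > 0 else lag_ms
            )
            lead_spec = EventSpec(kind=lead_kind)
            trail_spec = EventSpec(kind=trail_kind)
            span = (
                lead_spec.duration_ms / 2000.0
                + lag / 1000.0
                + trail_spec.duration_ms / 2000.0
            )
            key = f"{lead_kind}:{lead_spec.channel_role}"
            peak = _place_time(
                rng,
                placement_intervals(NREM),
                span + 0.1,
                occupied.get(key, []),
                min_gap=0.5,
            )
            if peak is None:
                warnings.warn("could not place coupled pair; skipping")
                continue
            i_lead = embed(lead_spec, peak)
            i_trail = embed(trail_spec, peak + lag / 1000.0)
            gt.coupled_tuples.append((i_lead, i_trail))

    # phase-locked ripples
    if config.phase_spec is not None:
        ps = config.phase_spec
        locked = [
            s for s in config.event_specs if s.kind == RIPPLE and s.time is None
        ]
        for spec in locked:
            phase = np.degrees(
                rng.vonmises(np.radians(ps.target_phase_deg), ps.concentration)
            ) % 360.0
            # SO = cos(2*pi*f*t): phase phi occurs at t = (k + phi/360)/f
            half = spec.duration_ms / 2000.0 + 0.05
            cycles = np.arange(1, int(config.duration * ps.so_frequency) - 1)
            times = (cycles + phase / 360.0) / ps.so_frequency
            ok = times[(times > half) & (times < config.duration - half)]
            key = f"{RIPPLE}:{spec.channel_role}"
            occ = occupied.get(key, [])
            free = [
                tt
                for tt in ok
                if all(tt + half <= s or tt - half >= e for s, e in occ)
            ]
            if not free:
                warnings.warn("no free slot for phase-locked ripple; skipping")
                continue
            peak = free[rng.integers(len(free))]
            idx = embed(spec, peak)
            gt.event_phases.append((idx, phase))
        remaining = [s for s in config.event_specs if s not in locked]
    else:
        remaining = list(config.event_specs)

    # free events
    for spec in remaining:
        if spec.time is not None:
            embed(spec, spec.time)
        else:
            half = spec.duration_ms / 2000.0
            key = f"{spec.kind}:{spec.channel_role}"
            peak = _place_time(
                rng,
                placement_intervals(spec.state),
                half + 0.05,
                occupied.get(key, []),
            )
            if peak is None:
                warnings.warn(f"could not place {spec.kind} event; skipping")
                continue
            embed(spec, peak)

    # ground-truth events sorted by start time, remapping indices
    order = np.argsort([e.start for e in gt.events], kind="stable")
    remap = {old: new for new, old in enumerate(order)}
    gt.events = [gt.events[i] for i in order]
    gt.coupled_tuples = [tuple(remap[i] for i in tp) for tp in gt.coupled_tuples]
    gt.event_phases = [(remap[i], ph) for i, ph in gt.event_phases]

    bundle = SignalBundle(
        samples=np.vstack([channels["HPC"], channels["PFC"], acc]),
        fs=fs,
        channel_roles=["HPC", "PFC", "ACC_X", "ACC_Y", "ACC_Z"],
    )
    return bundle, gt
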