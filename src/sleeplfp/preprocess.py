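"""Downsampling, zero-phase band-pass filtering, and artifact blanking.

Two recording regimes are supported: *chronic* (freely moving, 30 kHz
acquisition analysed at 2.5 kHz) and *acute* (urethane anesthesia, analysed
at 600 Hz).  All filters are 3rd-order Butterworth prototypes applied
forward-backward (zero phase).  Artifact blanking replaces suprathreshold
excursions — plus regime-specific buildup/washout windows — with the mean of
the clean signal, and is applied after band-pass filtering so the blanking
discontinuities never enter the filters.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .core import ArtifactMask, InvalidArgumentError, SignalBundle, merge_intervals

__all__ = [
    "downsample",
    "bandpass",
    "band_sd",
    "blank_artifacts_chronic",
    "blank_artifacts_acute",
    "CHRONIC_DOWNSAMPLE",
    "ACUTE_DOWNSAMPLE",
]

#: (target_fs, anti-alias cutoff Hz, filter order)
CHRONIC_DOWNSAMPLE = (2500.0, 1250.0, 3)
ACUTE_DOWNSAMPLE = (600.0, 300.0, 3)


def downsample(
    bundle: SignalBundle,
    target_fs: float,
    cutoff: float | None = None,
    order: int = 3,
) -> SignalBundle:
    """Anti-alias low-pass (zero phase) then decimate to ``target_fs``.

    ``cutoff`` defaults to ``target_fs / 2``.  The decimation ratio
    ``fs / target_fs`` must be (close to) an integer.
    """
    fs = bundle.fs
    if cutoff is None:
        cutoff = target_fs / 2.0
    if cutoff >= fs / 2:
        raise InvalidArgumentError("cutoff must be below the input Nyquist")
    if target_fs <= 0 or target_fs > fs:
        raise InvalidArgumentError("target_fs must be in (0, fs]")
    ratio = fs / target_fs
    q = int(round(ratio))
    if abs(ratio - q) > 1e-6:
        raise InvalidArgumentError(
            f"fs/target_fs = {ratio} is not an integer decimation factor"
        )
    sos = sps.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, bundle.samples, axis=1)
    return SignalBundle(
        samples=np.ascontiguousarray(filtered[:, ::q]),
        fs=target_fs,
        channel_roles=list(bundle.channel_roles),
        units=bundle.units,
        session_meta=dict(bundle.session_meta),
    )


def bandpass(
    x: np.ndarray, fs: float, low: float, high: float, order: int = 3
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of the stated prototype order."""
    if not 0 < low < high < fs / 2:
        raise InvalidArgumentError(
            f"invalid band ({low}, {high}) Hz for fs={fs} Hz"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=np.float64))


def band_sd(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """SD of the signal restricted to ``band`` (used for detection thresholds)."""
    return float(np.std(bandpass(x, fs, band[0], min(band[1], 0.999 * fs / 2))))


def _mask_from_bool(flag: np.ndarray, fs: float, offset_s: float = 0.0):
    """Convert a boolean sample mask into merged (start, end) second intervals."""
    if not flag.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], flag.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]
    return merge_intervals(
        [(offset_s + s / fs, offset_s + e / fs) for s, e in zip(starts, ends)]
    )


def blank_artifacts_chronic(
    bout: np.ndarray,
    fs: float,
    amp_threshold: float | None = None,
    buildup: float = 1.0,
) -> tuple[np.ndarray, ArtifactMask]:
    """Blank chronic-regime artifacts in one (already band-passed) bout.

    Samples with ``|value| > amp_threshold`` — plus a ``buildup``-second
    window preceding each excursion — are replaced by the mean of the
    below-threshold samples of the bout.  The default threshold is 8x the
    bout's robust SD (1.4826*MAD), a stand-in for the visually chosen
    per-session threshold of a human operator.
    """
    bout = np.asarray(bout, dtype=np.float64)
    if bout.size == 0:
        raise InvalidArgumentError("bout must be non-empty")
    if amp_threshold is None:
        mad = np.median(np.abs(bout - np.median(bout)))
        amp_threshold = 8.0 * 1.4826 * mad
    if amp_threshold <= 0:
        raise InvalidArgumentError("amp_threshold must be positive")
    bad = np.abs(bout) > amp_threshold
    if not bad.any():
        return bout.copy(), ArtifactMask([], replacement_value=float(np.mean(bout)))
    if buildup > 0:
        nb = int(round(buildup * fs))
        starts = np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8)))) == 1)
        for s in starts:
            bad[max(0, s - nb) : s] = True
    clean_mean = float(np.mean(bout[~bad])) if (~bad).any() else 0.0
    out = bout.copy()
    out[bad] = clean_mean
    return out, ArtifactMask(_mask_from_bool(bad, fs), replacement_value=clean_mean)


def blank_artifacts_acute(
    hpc: np.ndarray,
    pfc: np.ndarray,
    fs: float,
    threshold: float,
    buildup: float = 0.5,
    washout: float = 3.5,
    discard_head: float = 900.0,
    filtered: dict[str, np.ndarray] | None = None,
) -> tuple[dict[str, np.ndarray], ArtifactMask]:
    """Acute-regime artifact blanking on the HPC + PFC channel pair.

    The first ``discard_head`` seconds are dropped (probe stabilisation).
    An artifact sample is one where the sum of absolute values across the two
    *unfiltered* channels exceeds ``threshold``; the window
    ``[t - buildup, t + washout]`` around each artifact is replaced with the
    artifact-free mean.  ``filtered`` may carry extra (already band-passed)
    versions of the channels to be blanked with the same mask — band-pass for
    ripple detection must happen before blanking.

    Returns a dict of blanked channels (keys ``HPC``, ``PFC`` plus any
    ``filtered`` keys) and the mask in seconds relative to the trimmed
    signal.
    """
    hpc = np.asarray(hpc, dtype=np.float64)
    pfc = np.asarray(pfc, dtype=np.float64)
    if hpc.shape != pfc.shape:
        raise InvalidArgumentError("HPC and PFC channels must have equal length")
    n_head = int(round(discard_head * fs))
    if n_head >= hpc.size:
        raise InvalidArgumentError("discard_head is at least the recording length")
    chans = {"HPC": hpc[n_head:], "PFC": pfc[n_head:]}
    if filtered:
        for k, v in filtered.items():
            v = np.asarray(v, dtype=np.float64)
            if v.size != hpc.size:
                raise InvalidArgumentError("filtered channels must match raw length")
            chans[k] = v[n_head:]
    n = chans["HPC"].size
    bad = (np.abs(chans["HPC"]) + np.abs(chans["PFC"])) > threshold
    if bad.any():
        nb, nw = int(round(buildup * fs)), int(round(washout * fs))
        idx = np.flatnonzero(bad)
        grown = np.zeros(n, dtype=bool)
        for i in idx:
            grown[max(0, i - nb) : min(n, i + nw + 1)] = True
        bad = grown
    out: dict[str, np.ndarray] = {}
    for k, v in chans.items():
        clean_mean = float(np.mean(v[~bad])) if (~bad).any() else 0.0
        blanked = v.copy()
        blanked[bad] = clean_mean
        out[k] = blanked
    return out, ArtifactMask(_mask_from_bool(bad, fs))
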