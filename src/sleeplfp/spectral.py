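"""Power spectra and aperiodic (1/f) parameterization.

Power spectral densities are Welch estimates with a Hann taper (4 s windows,
0.25 s overlap), a 50 Hz line-noise notch, and a 0-100 Hz grid in 0.25 Hz
steps, reported as log10 power.

The aperiodic parameterization models the log-power spectrum as a linear
aperiodic component in log10-log10 coordinates plus Gaussian oscillatory
peaks (in log10 power over linear frequency):

    log10 P(f) = offset - exponent * log10 f + sum_k h_k exp(-(f-c_k)^2 / (2 s_k^2))

fitted iteratively: a robust line first, Gaussians on the residual
largest-first (height >= 0.05, width 1-8 Hz), then the line refit on the
peak-subtracted spectrum.  The negative slope (the exponent) is the standard
spectral proxy for the excitation/inhibition ratio — a flatter slope means
a higher E/I ratio — and the offset tracks overall activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.optimize import curve_fit

from .core import (
    LONG,
    SHORT,
    InvalidArgumentError,
    OscillationEvent,
    SignalBundle,
)

__all__ = [
    "SpectralEstimate",
    "AperiodicFit",
    "compute_psd",
    "fit_aperiodic",
    "aperiodic_model",
    "event_triggered_spectra",
]


@dataclass
class SpectralEstimate:
    frequencies: np.ndarray  # Hz, strictly increasing
    log10_power: np.ndarray
    meta: dict = field(default_factory=dict)

    def linear_power(self) -> np.ndarray:
        return 10.0**self.log10_power


@dataclass
class AperiodicFit:
    offset: float  # log10 power at log10 f = 0
    exponent: float  # slope = -exponent in log-log coordinates
    peaks: list[tuple[float, float, float]]  # (center Hz, height, width Hz)
    fit_range: tuple[float, float]
    r_squared: float


def compute_psd(
    segment: np.ndarray,
    fs: float,
    window_s: float = 4.0,
    overlap_s: float = 0.25,
    notch_hz: float | None = 50.0,
    fmax: float = 100.0,
    notch_q: float = 30.0,
) -> SpectralEstimate:
    """Welch PSD (Hann taper) of one segment, as log10 power up to ``fmax``.

    A 4 s window gives the 0.25 Hz grid natively.  Segments shorter than one
    window are zero-padded to a single window with a warning.
    """
    x = np.asarray(segment, dtype=np.float64)
    if notch_hz is not None and notch_hz < fs / 2:
        b, a = sps.iirnotch(notch_hz, Q=notch_q, fs=fs)
        x = sps.filtfilt(b, a, x)
    nperseg = int(round(window_s * fs))
    if x.size < nperseg:
        warnings.warn("segment shorter than the window; zero-padding one window")
        x = np.pad(x, (0, nperseg - x.size))
    freqs, psd = sps.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap_s * fs)),
        detrend="constant",
    )
    keep = freqs <= fmax
    log_p = np.log10(np.maximum(psd[keep], 1e-300))
    return SpectralEstimate(
        frequencies=freqs[keep],
        log10_power=log_p,
        meta={
            "window_s": window_s,
            "overlap_s": overlap_s,
            "taper": "hann",
            "notch_hz": notch_hz,
        },
    )


def aperiodic_model(
    freqs: np.ndarray,
    offset: float,
    exponent: float,
    peaks: Sequence[tuple[float, float, float]] = (),
) -> np.ndarray:
    """log10 power of the aperiodic line plus Gaussian peaks."""
    out = offset - exponent * np.log10(freqs)
    for center, height, width in peaks:
        sigma = width / 2.0
        out = out + height * np.exp(-((freqs - center) ** 2) / (2 * sigma**2))
    return out


def _line_fit(logf: np.ndarray, logp: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(logf, logp, 1)
    return float(intercept), float(-slope)  # (offset, exponent)


def _robust_line_fit(logf: np.ndarray, logp: np.ndarray) -> tuple[float, float]:
    """Line fit ignoring points sitting above the bulk (oscillatory peaks)."""
    offset, exponent = _line_fit(logf, logp)
    resid = logp - (offset - exponent * logf)
    resid_pos = np.clip(resid, 0, None)
    thresh = np.percentile(resid_pos, 2.5)
    mask = resid_pos <= thresh + 1e-12
    if mask.sum() >= 2:
        offset, exponent = _line_fit(logf[mask], logp[mask])
    return offset, exponent


def fit_aperiodic(
    spec: SpectralEstimate,
    fit_range: tuple[float, float] = (1.0, 100.0),
    peak_width_limits: tuple[float, float] = (1.0, 8.0),
    min_peak_height: float = 0.05,
    max_peaks: int = 6,
    exclude: tuple[float, float] | None = (45.0, 55.0),
) -> AperiodicFit:
    """Parameterize a log-power spectrum into aperiodic line + Gaussian peaks.

    Steps: (i) robust line fit of log10 power on log10 frequency; (ii)
    Gaussian peaks extracted from the residual largest-first while the
    residual maximum stays >= ``min_peak_height``, widths clipped to
    ``peak_width_limits``, at most ``max_peaks``, then refined jointly by
    least squares; (iii) line refit on the peak-subtracted spectrum.  The
    ``exclude`` band (notch neighbourhood) is left out of the fit grid.
    """
    freqs = np.asarray(spec.frequencies, dtype=np.float64)
    power = np.asarray(spec.log10_power, dtype=np.float64)
    if not np.all(np.isfinite(power)):
        raise InvalidArgumentError("non-finite power values")
    sel = (freqs >= fit_range[0]) & (freqs <= fit_range[1]) & (freqs > 0)
    if exclude is not None:
        sel &= ~((freqs >= exclude[0]) & (freqs <= exclude[1]))
    f, p = freqs[sel], power[sel]
    if f.size < 4:
        raise InvalidArgumentError("too few points in fit range")
    logf = np.log10(f)

    offset, exponent = _robust_line_fit(logf, p)

    # iterative peak guesses on the flattened spectrum
    flat = p - (offset - exponent * logf)
    guesses: list[tuple[float, float, float]] = []
    min_sigma, max_sigma = peak_width_limits[0] / 2, peak_width_limits[1] / 2
    for _ in range(max_peaks):
        i = int(np.argmax(flat))
        height = flat[i]
        if height < min_peak_height:
            break
        center = f[i]
        half = height / 2
        j = i
        while j + 1 < f.size and flat[j + 1] > half:
            j += 1
        k = i
        while k - 1 >= 0 and flat[k - 1] > half:
            k -= 1
        fwhm = max(f[j] - f[k], np.min(np.diff(f)))
        sigma = np.clip(fwhm / 2.355, min_sigma, max_sigma)
        guesses.append((center, height, sigma))
        flat = flat - height * np.exp(-((f - center) ** 2) / (2 * sigma**2))

    peaks: list[tuple[float, float, float]] = []
    if guesses:
        flat0 = p - (offset - exponent * logf)

        def gauss_sum(x, *params):
            y = np.zeros_like(x)
            for c, h, s in zip(params[::3], params[1::3], params[2::3]):
                y = y + h * np.exp(-((x - c) ** 2) / (2 * s**2))
            return y

        p0 = [v for g in guesses for v in g]
        lo = [v for c, h, s in guesses for v in (c - 2 * s, 0.0, min_sigma)]
        hi = [
            v
            for c, h, s in guesses
            for v in (c + 2 * s, max(2 * h, 1.0), max_sigma)
        ]
        try:
            popt, _ = curve_fit(
                gauss_sum, f, flat0, p0=p0, bounds=(lo, hi), maxfev=5000
            )
            fitted = list(zip(popt[::3], popt[1::3], popt[2::3]))
        except RuntimeError:
            fitted = guesses
        peaks = [
            (float(c), float(h), float(2 * s))
            for c, h, s in fitted
            if h >= min_peak_height
        ]

    # refit the aperiodic component on the peak-subtracted spectrum
    peak_part = aperiodic_model(f, 0.0, 0.0, peaks)
    offset, exponent = _line_fit(logf, p - peak_part)

    model = aperiodic_model(f, offset, exponent, peaks)
    ss_res = float(np.sum((p - model) ** 2))
    ss_tot = float(np.sum((p - p.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return AperiodicFit(
        offset=offset,
        exponent=exponent,
        peaks=sorted(peaks, key=lambda pk: -pk[1]),
        fit_range=fit_range,
        r_squared=r2,
    )


def event_triggered_spectra(
    bundle: SignalBundle,
    events: Sequence[OscillationEvent],
    nrem_intervals: Sequence[tuple[float, float]],
    n_baseline: int = 50,
    seed: int = 0,
    window_s: float = 4.0,
    regions: tuple[str, ...] = ("HPC", "PFC"),
    **psd_kwargs,
) -> dict[tuple[str, str], SpectralEstimate]:
    """Average spectra in windows centered on ripple peaks, per length class.

    For every event a ``window_s`` window centered on the peak is extracted
    on each region's channel; log10 spectra are averaged within class
    (``SHORT``/``LONG``).  The ``baseline`` class averages ``n_baseline``
    random NonREM windows of the same length (seeded).  Events too close to
    a recording edge are excluded with a warning.
    """
    rng = np.random.default_rng(seed)
    half = window_s / 2.0
    classes: dict[str, list[float]] = {SHORT: [], LONG: []}
    n_edge = 0
    for e in events:
        if e.peak - half < 0 or e.peak + half > bundle.duration:
            n_edge += 1
            continue
        if e.length_class in classes:
            classes[e.length_class].append(e.peak)
    if n_edge:
        warnings.warn(f"{n_edge} events too close to the recording edge; excluded")

    baseline_centers: list[float] = []
    usable = [(s + half, e - half) for s, e in nrem_intervals if e - s > window_s]
    if usable:
        lengths = np.array([e - s for s, e in usable])
        for _ in range(n_baseline):
            i = rng.choice(len(usable), p=lengths / lengths.sum())
            baseline_centers.append(rng.uniform(*usable[i]))
    classes["baseline"] = baseline_centers

    out: dict[tuple[str, str], SpectralEstimate] = {}
    for region in regions:
        x = bundle.channel(region)
        for cls, centers in classes.items():
            if not centers:
                continue
            spectra = []
            for c in centers:
                i0 = int(round((c - half) * bundle.fs))
                seg = x[i0 : i0 + int(round(window_s * bundle.fs))]
                est = compute_psd(seg, bundle.fs, window_s=window_s, **psd_kwargs)
                spectra.append(est.log10_power)
            out[(cls, region)] = SpectralEstimate(
                frequencies=est.frequencies,
                log10_power=np.mean(spectra, axis=0),
                meta={"n_windows": len(centers), "class": cls, "region": region},
            )
    return out
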