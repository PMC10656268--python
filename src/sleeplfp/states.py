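"""Sleep-state bookkeeping and automatic anesthesia state classification.

Chronic recordings arrive with a manually scored hypnogram (1 s epochs,
WAKE/NREM/INTERMEDIATE/REM) which this module only ingests and summarizes.
Acute (anesthesia) recordings have no wakefulness, so a two-state classifier
labels 10 s epochs as NonREM-like or REM-like from multitaper spectral
features via PCA + 2-means, with amplitude-outlier epochs flagged as
artifacts first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .core import (
    ARTIFACT,
    NREM_LIKE,
    REM_LIKE,
    WAKE,
    Hypnogram,
    InvalidArgumentError,
    SignalBundle,
)

__all__ = [
    "ArchitectureSummary",
    "architecture",
    "epoch_features",
    "flag_artifact_epochs",
    "classify_sleep_like",
    "FEATURE_BANDS",
]

#: spectral feature bands (Hz); ranges sit lower than the natural-sleep
#: literature because urethane anesthesia slows cortical activity
FEATURE_BANDS = {
    "so_power": (0.1, 1.0),
    "delta_power": (1.0, 3.0),
    "theta_power": (3.0, 6.0),
    "low_beta": (10.0, 20.0),
    "low_gamma": (30.0, 45.0),
    "high_gamma": (55.0, 80.0),
    "ripple_power": (90.0, 300.0),
}

_NON_SLEEP = (WAKE, ARTIFACT)


@dataclass
class ArchitectureSummary:
    tst: float
    pct_state: dict[str, float]
    bouts: list[tuple[str, float, float]]  # (state, start s, duration s)
    bout_durations: dict[str, list[float]]  # only bouts > min_bout
    transitions: dict[tuple[str, str], int]
    binned_pct: pd.DataFrame  # index bin, columns sleep states, % of bin TST
    tst_zero: bool = False

    def to_dict(self) -> dict:
        return {
            "tst_s": self.tst,
            "pct_state": self.pct_state,
            "n_bouts": {k: len(v) for k, v in self.bout_durations.items()},
            "transitions": {f"{a}->{b}": c for (a, b), c in self.transitions.items()},
            "tst_zero": self.tst_zero,
        }


def architecture(
    hyp: Hypnogram, min_bout: float = 4.0, bin_width: float = 2700.0
) -> ArchitectureSummary:
    """Total sleep time, state percentages, bouts, transitions, binned %.

    Bouts are maximal runs of one state; the bout-duration distribution keeps
    only bouts strictly longer than ``min_bout`` (default 4 s).  Transitions
    are counted at every change between consecutive labels.  ``binned_pct``
    gives the % of each bin's sleep time per sleep state, with a partial
    final bin normalized by its own duration.
    """
    states = hyp.states
    if not states:
        raise InvalidArgumentError("hypnogram is empty")
    eps = hyp.epoch_s

    sleep_states = sorted({s for s in states if s not in _NON_SLEEP})
    tst = sum(1 for s in states if s not in _NON_SLEEP) * eps
    tst_zero = tst == 0
    pct_state = {
        s: (0.0 if tst_zero else 100.0 * states.count(s) * eps / tst)
        for s in sleep_states
    }

    bouts: list[tuple[str, float, float]] = []
    run_start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[run_start]:
            bouts.append((states[run_start], run_start * eps, (i - run_start) * eps))
            run_start = i
    bout_durations: dict[str, list[float]] = {s: [] for s in sleep_states}
    for state, _, dur in bouts:
        if state in bout_durations and dur > min_bout:
            bout_durations[state].append(dur)

    transitions: dict[tuple[str, str], int] = {}
    for a, b in zip(states[:-1], states[1:]):
        if a != b:
            transitions[(a, b)] = transitions.get((a, b), 0) + 1

    n_bins = int(np.ceil(len(states) * eps / bin_width))
    rows = []
    for b in range(n_bins):
        i0 = int(b * bin_width / eps)
        i1 = min(len(states), int((b + 1) * bin_width / eps))
        chunk = states[i0:i1]
        bin_tst = sum(1 for s in chunk if s not in _NON_SLEEP) * eps
        row = {
            s: (0.0 if bin_tst == 0 else 100.0 * chunk.count(s) * eps / bin_tst)
            for s in sleep_states
        }
        rows.append(row)
    binned = pd.DataFrame(rows, index=pd.RangeIndex(n_bins, name="bin"))

    return ArchitectureSummary(
        tst=tst,
        pct_state=pct_state,
        bouts=bouts,
        bout_durations=bout_durations,
        transitions=transitions,
        binned_pct=binned,
        tst_zero=tst_zero,
    )


# ---------------------------------------------------------------------------
# multitaper epoch features


def multitaper_psd(
    x: np.ndarray, fs: float, nw: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalue-weighted DPSS multitaper PSD (one-sided, µV²/Hz)."""
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    k = max(1, int(2 * nw) - 1)
    tapers, ratios = sps.windows.dpss(n, NW=nw, Kmax=k, return_ratios=True)
    spectra = np.abs(np.fft.rfft(tapers * x[None, :], axis=1)) ** 2 / fs
    spectra[:, 1:] *= 2.0
    if n % 2 == 0:
        spectra[:, -1] /= 2.0
    psd = np.average(spectra, axis=0, weights=ratios)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, psd


def epoch_features(
    bundle: SignalBundle,
    epoch_s: float = 10.0,
    nw: float = 4.0,
    fmax: float = 100.0,
    step: float = 0.5,
    regions: tuple[str, ...] = ("HPC", "PFC"),
) -> pd.DataFrame:
    """Per-epoch band powers, theta/SO ratio and amplitude per region.

    Spectra are multitaper estimates (time-bandwidth ``nw``) evaluated on a
    0-``fmax`` Hz grid in ``step`` Hz increments; band powers sum the grid
    bins inside each band.  Columns are ``{region}_{feature}``.
    """
    n_per = int(round(epoch_s * bundle.fs))
    if n_per > bundle.n_samples:
        raise InvalidArgumentError("epoch longer than recording")
    n_epochs = bundle.n_samples // n_per
    grid = np.arange(0.0, fmax + step / 2, step)
    rows = []
    for e in range(n_epochs):
        sl = slice(e * n_per, (e + 1) * n_per)
        row: dict[str, float] = {"epoch_index": e}
        for region in regions:
            x = bundle.channel(region)[sl]
            freqs, psd = multitaper_psd(x, bundle.fs, nw=nw)
            on_grid = np.interp(grid, freqs, psd)
            for name, (lo, hi) in FEATURE_BANDS.items():
                sel = (grid >= lo) & (grid < hi)
                row[f"{region}_{name}"] = float(on_grid[sel].sum())
            so = row[f"{region}_so_power"]
            row[f"{region}_theta_so_ratio"] = (
                row[f"{region}_theta_power"] / so if so > 0 else np.nan
            )
            row[f"{region}_amplitude"] = float(np.max(np.abs(x)))
        rows.append(row)
    return pd.DataFrame(rows).set_index("epoch_index")


def flag_artifact_epochs(features: pd.DataFrame) -> np.ndarray:
    """Median ± 3 scaled-MAD outlier rule on epoch amplitudes.

    An epoch is flagged when any region's amplitude deviates from that
    region's median by more than three scaled MADs (1.4826·MAD).  With a
    degenerate MAD of zero, any non-zero deviation flags the epoch (strict
    inequality keeps identical amplitudes unflagged).
    """
    if len(features) < 3:
        raise InvalidArgumentError("need at least 3 epochs")
    amp_cols = [c for c in features.columns if c.endswith("_amplitude")]
    flags = np.zeros(len(features), dtype=bool)
    for c in amp_cols:
        a = features[c].to_numpy()
        med = np.median(a)
        mad = 1.4826 * np.median(np.abs(a - med))
        flags |= np.abs(a - med) > 3.0 * mad
    return flags


def classify_sleep_like(
    features: pd.DataFrame,
    seed: int = 0,
    artifact_flags: np.ndarray | None = None,
    epoch_s: float = 10.0,
) -> Hypnogram:
    """Two-state (NonREM-like / REM-like) classification of anesthesia epochs.

    Features are z-scored, projected on the first two principal components,
    and split by 2-means in the PC1-PC2 plane.  PC1's sign is fixed so that
    the summed loading of the slow-oscillation power features is positive;
    the cluster with the higher mean PC1 — high amplitude and SO power, the
    NonREM signature — is labeled NonREM-like.  Flagged artifact epochs are
    excluded from the fit and labeled ARTIFACT.
    """
    if artifact_flags is None:
        artifact_flags = flag_artifact_epochs(features)
    artifact_flags = np.asarray(artifact_flags, dtype=bool)
    keep = ~artifact_flags
    if keep.sum() < 2:
        raise InvalidArgumentError("need at least 2 non-artifact epochs")
    cols = [c for c in features.columns if c != "epoch_index"]
    X = features.loc[keep, cols].to_numpy(dtype=np.float64)
    X = np.nan_to_num(X, nan=0.0)
    X = StandardScaler().fit_transform(X)
    pca = PCA(n_components=2, random_state=seed)
    pcs = pca.fit_transform(X)
    so_idx = [i for i, c in enumerate(cols) if c.endswith("_so_power")]
    for comp in range(2):
        anchor = (
            pca.components_[comp, so_idx].sum()
            if comp == 0 and so_idx
            else pca.components_[comp, np.argmax(np.abs(pca.components_[comp]))]
        )
        if anchor < 0:
            pcs[:, comp] *= -1
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(pcs)
    mean_pc1 = [pcs[labels == k, 0].mean() for k in (0, 1)]
    nrem_cluster = int(np.argmax(mean_pc1))
    states = np.full(len(features), ARTIFACT, dtype=object)
    states[keep] = np.where(labels == nrem_cluster, NREM_LIKE, REM_LIKE)
    return Hypnogram(states=list(states), epoch_s=epoch_s)
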