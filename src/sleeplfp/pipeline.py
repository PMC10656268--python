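"""Configuration-driven end-to-end session analysis.

``run_session`` chains preprocess -> sleep states -> oscillation detection ->
event bookkeeping -> coupling -> spectral analysis -> behavior on one
recording session and writes CSV/JSON outputs plus a machine-readable run
manifest (config hash, seed, stage status and counts).  Re-running with the
same configuration reproduces identical outputs.

``selftest`` runs a fast synthetic end-to-end check of the main pipeline
properties and reports per-property pass/fail.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    NREM,
    NREM_LIKE,
    WAKE,
    Hypnogram,
    SignalBundle,
    events_to_frame,
)
from .coupling import (
    SEQUENCE_WINDOWS_MS,
    assign_event_ids,
    cooccurrence,
    detect_d_swr,
    detect_pairs,
    detect_triplets,
    fraction_in_sequences,
    phase_locking_test,
    so_phase_at_events,
)
from .detect import (
    ACUTE_RIPPLE,
    CHRONIC_RIPPLE,
    detect_delta_waves,
    detect_quiet_wake_ripples,
    detect_ripples,
    detect_spindles,
    ripple_threshold,
)
from .events import bin_and_normalize, standard_sleep_bins
from .preprocess import bandpass, downsample
from .spectral import compute_psd, event_triggered_spectra, fit_aperiodic
from .states import classify_sleep_like, epoch_features, flag_artifact_epochs

__all__ = ["PipelineConfig", "run_session", "selftest"]

REGIME_DEFAULTS = {
    "chronic": {
        "target_fs": 2500.0,
        "cutoff": 1250.0,
        "ripple": CHRONIC_RIPPLE,
        "epoch_s": 1.0,
        "nrem_state": NREM,
    },
    "acute": {
        "target_fs": 600.0,
        "cutoff": 300.0,
        "ripple": ACUTE_RIPPLE,
        "epoch_s": 10.0,
        "nrem_state": NREM_LIKE,
    },
}

ALL_STAGES = (
    "preprocess",
    "states",
    "detect",
    "features",
    "coupling",
    "spectral",
    "behavior",
)


@dataclass
class PipelineConfig:
    regime: str = "chronic"
    bundle_path: str | None = None
    hypnogram_path: str | None = None  # chronic: manual scores (1 s epochs)
    behavior_csv: str | None = None
    output_dir: str = "session_out"
    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in ALL_STAGES}
    )
    sd_multiplier: float | None = None
    threshold_offset_uv: float | None = None
    min_nrem_s: float = 0.0  # per-period NonREM required for thresholding
    n_baseline: int = 30

    def __post_init__(self) -> None:
        if self.regime not in REGIME_DEFAULTS:
            raise ValueError(f"unknown regime {self.regime!r}")
        for s in self.stages:
            if s not in ALL_STAGES:
                raise ValueError(f"unknown stage {s!r}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """A stage is missing a mandatory input; message names the stage."""


def run_session(
    config: PipelineConfig,
    bundle: SignalBundle | None = None,
    hypnogram: Hypnogram | None = None,
) -> dict:
    """Run the full session analysis; returns the manifest dict.

    ``bundle``/``hypnogram`` may be passed in memory; otherwise they load
    from the paths in the config.  Outputs land in ``config.output_dir``.
    """
    defaults = REGIME_DEFAULTS[config.regime]
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "regime": config.regime,
        "stages": {},
    }
    on = config.stages

    if bundle is None:
        if config.bundle_path is None:
            raise StageError("preprocess: no input bundle")
        bundle = SignalBundle.load(config.bundle_path)

    # -- preprocess -----------------------------------------------------
    if on.get("preprocess", True):
        if bundle.fs > defaults["target_fs"]:
            bundle = downsample(
                bundle, defaults["target_fs"], defaults["cutoff"], order=3
            )
        manifest["stages"]["preprocess"] = {
            "status": "complete",
            "fs": bundle.fs,
            "duration_s": bundle.duration,
        }

    # -- sleep states ---------------------------------------------------
    if on.get("states", True):
        if config.regime == "chronic":
            if hypnogram is None:
                if config.hypnogram_path is None:
                    raise StageError("states: chronic regime needs a manual hypnogram")
                hypnogram = Hypnogram.from_csv(
                    config.hypnogram_path, epoch_s=defaults["epoch_s"]
                )
        else:
            feats = epoch_features(bundle, epoch_s=defaults["epoch_s"])
            flags = flag_artifact_epochs(feats)
            hypnogram = classify_sleep_like(
                feats, seed=config.seed, artifact_flags=flags,
                epoch_s=defaults["epoch_s"],
            )
        hypnogram.to_csv(out / "hypnogram.csv")
        manifest["stages"]["states"] = {
            "status": "complete",
            "n_epochs": len(hypnogram.states),
        }
    if hypnogram is None:
        raise StageError("detect: needs the states stage (hypnogram missing)")

    nrem_state = defaults["nrem_state"]
    nrem_ivs = hypnogram.intervals(nrem_state)

    # -- oscillation detection ------------------------------------------
    ripples = spindles = deltas = qw_ripples = None
    if on.get("detect", True):
        cfg = defaults["ripple"]
        sd_mult = config.sd_multiplier or cfg.sd_multiplier
        offset = (
            config.threshold_offset_uv
            if config.threshold_offset_uv is not None
            else cfg.offset
        )
        hpc_filt = bandpass(bundle.channel("HPC"), bundle.fs, *cfg.band)
        if not nrem_ivs:
            raise StageError("detect: no NonREM epochs in the hypnogram")
        nrem_concat = np.concatenate(
            [
                hpc_filt[int(s * bundle.fs) : int(e * bundle.fs)]
                for s, e in nrem_ivs
            ]
        )
        threshold = ripple_threshold(
            [nrem_concat], bundle.fs, sd_mult, offset, min_nrem_s=config.min_nrem_s
        )
        all_ripples = detect_ripples(
            hpc_filt,
            bundle.fs,
            threshold,
            cfg.min_duration_ms,
            cfg.closeness_ms,
            cfg.boundary_fraction,
            context=nrem_state,
        )
        in_nrem = lambda t: any(s <= t < e for s, e in nrem_ivs)  # noqa: E731
        ripples = [e for e in all_ripples if in_nrem(e.peak)]

        pfc = bundle.channel("PFC")
        spindles = [
            e
            for e in detect_spindles(
                bandpass(pfc, bundle.fs, 9.0, 20.0), bundle.fs, context=nrem_state
            )
            if in_nrem(e.peak)
        ]
        deltas = [
            e
            for e in detect_delta_waves(
                bandpass(pfc, bundle.fs, 1.0, 6.0), bundle.fs, context=nrem_state
            )
            if in_nrem(e.peak)
        ]

        qw_ripples = []
        wake_ivs = hypnogram.intervals(WAKE)
        if config.regime == "chronic" and wake_ivs:
            acc = (
                np.vstack(
                    [bundle.channel(r) for r in ("ACC_X", "ACC_Y", "ACC_Z")]
                )
                if bundle.has_channel("ACC_X")
                else None
            )
            qw_ripples = detect_quiet_wake_ripples(
                hpc_filt,
                bundle.fs,
                wake_ivs,
                threshold,
                acc=acc,
                raw=bundle.channel("HPC"),
                nrem_bouts=nrem_ivs,
                min_duration_ms=cfg.min_duration_ms,
                closeness_ms=cfg.closeness_ms,
            )

        assign_event_ids(ripples, spindles, deltas, qw_ripples)
        events_to_frame(ripples + qw_ripples + spindles + deltas).to_csv(
            out / "events.csv", index=False
        )
        manifest["stages"]["detect"] = {
            "status": "complete",
            "threshold_uV": threshold,
            "n_ripples": len(ripples),
            "n_quiet_wake_ripples": len(qw_ripples),
            "n_spindles": len(spindles),
            "n_deltas": len(deltas),
        }

    # -- event bookkeeping ----------------------------------------------
    if on.get("features", True):
        if ripples is None:
            raise StageError("features: needs the detect stage")
        all_events = ripples + qw_ripples + spindles + deltas
        if bundle.duration >= 8 * 2700.0:
            schedule = standard_sleep_bins()
        else:
            schedule = [(1, 0.0, bundle.duration)]
        binned = bin_and_normalize(all_events, schedule, hypnogram, nrem_state)
        binned.to_csv(out / "binned_counts.csv", index=False)
        manifest["stages"]["features"] = {
            "status": "complete",
            "n_bins": len(schedule),
        }

    # -- coupling -------------------------------------------------------
    if on.get("coupling", True):
        if ripples is None:
            raise StageError("coupling: needs the detect stage")
        d_s = detect_pairs(deltas, spindles, SEQUENCE_WINDOWS_MS["D_S"], "D_S")
        d_r = detect_pairs(deltas, ripples, SEQUENCE_WINDOWS_MS["D_R"], "D_R")
        r_s = detect_pairs(ripples, spindles, SEQUENCE_WINDOWS_MS["R_S"], "R_S")
        drs = detect_triplets(d_r, r_s)
        rws, swr = cooccurrence(ripples, spindles)
        d_swr = detect_d_swr(d_s, swr)
        records = d_s + d_r + r_s + drs + rws + d_swr
        pd.DataFrame(
            {
                "sequence_type": [r.sequence_type for r in records],
                "member_ids": [
                    ";".join(map(str, r.member_ids)) for r in records
                ],
                "intervals_ms": [
                    ";".join(f"{v:.1f}" for v in r.inter_peak_intervals_ms)
                    for r in records
                ],
                "ripple_class": [r.ripple_length_class for r in records],
            }
        ).to_csv(out / "coupling_records.csv", index=False)
        fractions = fraction_in_sequences(ripples, records)

        phases = so_phase_at_events(
            bundle.channel("PFC"),
            bundle.fs,
            [e.peak for e in ripples],
            [e.event_id for e in ripples],
        )
        pd.DataFrame(
            {
                "event_id": [p.event_id for p in phases],
                "phase_deg": [p.phase_deg for p in phases],
            }
        ).to_csv(out / "ripple_so_phases.csv", index=False)
        locking = None
        if len(phases) >= 5:
            mean_dir, r_len, pval = phase_locking_test(phases)
            locking = {"mean_deg": mean_dir, "R": r_len, "p": pval}
        summary = {
            "counts": {
                t: sum(r.sequence_type == t for r in records)
                for t in ("D_S", "D_R", "R_S", "D_R_S", "SwR", "D_SwR")
            },
            "fractions": fractions,
            "phase_locking": locking,
        }
        (out / "coupling_summary.json").write_text(json.dumps(summary, indent=2))
        manifest["stages"]["coupling"] = {
            "status": "complete",
            **summary["counts"],
        }

    # -- spectral -------------------------------------------------------
    if on.get("spectral", True):
        fits = {}
        for region in ("HPC", "PFC"):
            x = bundle.channel(region)
            nrem_sig = np.concatenate(
                [x[int(s * bundle.fs) : int(e * bundle.fs)] for s, e in nrem_ivs]
            )
            est = compute_psd(nrem_sig, bundle.fs)
            fit = fit_aperiodic(est)
            fits[region] = {
                "offset": fit.offset,
                "exponent": fit.exponent,
                "r_squared": fit.r_squared,
                "peaks": fit.peaks,
            }
            pd.DataFrame(
                {"frequency_hz": est.frequencies, "log10_power": est.log10_power}
            ).to_csv(out / f"psd_nrem_{region.lower()}.csv", index=False)
        (out / "aperiodic_fits.json").write_text(json.dumps(fits, indent=2))
        if ripples:
            spectra = event_triggered_spectra(
                bundle,
                ripples,
                nrem_ivs,
                n_baseline=config.n_baseline,
                seed=config.seed,
            )
            rows = []
            for (cls, region), est in spectra.items():
                for fq, lp in zip(est.frequencies, est.log10_power):
                    rows.append(
                        {
                            "class": cls,
                            "region": region,
                            "frequency_hz": fq,
                            "log10_power": lp,
                        }
                    )
            pd.DataFrame(rows).to_csv(out / "event_spectra.csv", index=False)
        manifest["stages"]["spectral"] = {"status": "complete", **fits}

    # -- behavior -------------------------------------------------------
    if on.get("behavior", True) and config.behavior_csv:
        from .behavior import read_trials_csv, session_table

        table = session_table(read_trials_csv(config.behavior_csv))
        table.to_csv(out / "behavior_table.csv", index=False)
        manifest["stages"]["behavior"] = {"status": "complete", "n_rows": len(table)}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


# ---------------------------------------------------------------------------
# selftest


def selftest(seed: int = 0, verbose: bool = True) -> dict[str, bool]:
    """Fast synthetic checks of the pipeline's core properties."""
    from .behavior import discrimination_index
    from .core import OscillationEvent, RIPPLE
    from .synth import EventSpec, SimConfig, generate_recording

    results: dict[str, bool] = {}
    rng = np.random.default_rng(seed)

    # aperiodic slope recovery on a short background
    from .synth import generate_background

    bg = generate_background(60.0, 500.0, 1.5, 2.0, seed)
    fit = fit_aperiodic(compute_psd(bg, 500.0))
    results["aperiodic_recovery"] = abs(fit.exponent - 1.5) < 0.15

    # ripple detector recall/precision on a small synthetic session
    fs = 1000.0
    cfg = SimConfig(
        duration=120.0,
        fs=fs,
        state_schedule=[(NREM, 120.0)],
        event_specs=[EventSpec(kind=RIPPLE, center_frequency=150.0) for _ in range(20)],
        seed=seed,
    )
    bundle, gt = generate_recording(cfg)
    filt = bandpass(bundle.channel("HPC"), fs, 100.0, 300.0)
    thr = ripple_threshold([filt], fs, 5.0, 5.0, min_nrem_s=0.0)
    det = detect_ripples(filt, fs, thr)
    hits = sum(
        any(g.start <= d.peak <= g.end for g in gt.events) for d in det
    )
    recall = hits / len(gt.events) if gt.events else 0.0
    precision = hits / len(det) if det else 0.0
    results["ripple_recall"] = recall >= 0.9
    results["ripple_precision"] = precision >= 0.9

    # pair detection equals brute force
    lead = [
        OscillationEvent("DELTA", "PFC", t, t, t, event_id=i)
        for i, t in enumerate(np.sort(rng.uniform(0, 60, 40)))
    ]
    trail = [
        OscillationEvent("SPINDLE", "PFC", t, t, t, event_id=100 + i)
        for i, t in enumerate(np.sort(rng.uniform(0, 60, 40)))
    ]
    fast = detect_pairs(lead, trail, (100.0, 1300.0), "D_S")
    brute = {
        (a.event_id, b.event_id)
        for a in lead
        for b in trail
        if 0.1 <= b.peak - a.peak <= 1.3
    }
    results["pair_oracle"] = {r.member_ids for r in fast} == brute

    # phase locking on concentrated phases
    phases = np.degrees(rng.vonmises(np.pi, 20.0, 50)) % 360
    mean_dir, r_len, p = phase_locking_test(phases)
    results["phase_locking"] = (
        min(abs(mean_dir - 180), 360 - abs(mean_dir - 180)) < 10 and p < 0.01
    )

    # worked examples
    results["discrimination_index"] = (
        discrimination_index(30, 10) == 0.5
        and discrimination_index(10, 10) == 0.0
        and discrimination_index(0, 20) == -1.0
    )

    if verbose:
        for name, ok in results.items():
            print(f"{name:>24}: {'PASS' if ok else 'FAIL'}")
    return results
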