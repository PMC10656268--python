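# sleeplfp

Analysis pipeline for rodent sleep electrophysiology: detection and
characterization of the NonREM oscillations that support memory
consolidation — hippocampal sharp-wave ripples, cortical sleep spindles and
delta waves — together with sleep-architecture statistics, automatic
classification of sleep-like states under anesthesia,
hippocampal–cortical coupling sequences, slow-oscillation phase locking,
aperiodic (1/f) spectral parameterization as an excitation/inhibition
proxy, and Object Space task behavior scores.

The package is aimed at systems-neuroscience labs analysing dual-site LFP
recordings (hippocampal CA1 + prelimbic cortex, plus a 3-axis
accelerometer). Every stage is driven by explicit, named parameters and is
validated against a ground-truthed synthetic-LFP generator, so the whole
pipeline is testable without any real recordings.

## What it computes

**Ripple detection.** The band-passed trace (100–300 Hz chronic, 90–200 Hz
under urethane) is reduced to its Hilbert envelope `e(t) = |H(x)(t)|`. The
detection threshold per study day is

```
theta = mean_p( m * SD_p ) + c
```

where `SD_p` is the SD of the concatenated filtered NonREM signal of trial
period *p*, `m = 5`, and `c = 5 µV`. A candidate is a suprathreshold run of
≥ 20 ms (chronic; 50 ms acute); candidates closer than 20 ms (80 ms acute)
merge; edges extend to the crossings of `theta/2`. Ripples are classed
SHORT (≤ 100 ms) or LONG (> 100 ms). Quiet-wake ripples add movement
(accelerometer resultant), locomotion-theta (5–10 Hz) and amplitude vetoes.

**Spindles and delta waves.** Spindles: 9–20 Hz envelope above a low
threshold for 0.4–3 s with a high-threshold excursion. Delta waves: 1–6 Hz
zero-crossing segments with a positive peak > 2 SD followed by a trough
< −1.5 SD.

**Coupling.** All ordered peak-lag motifs with inclusive windows —
D-S ∈ [100, 1300] ms, D-R ∈ [50, 400] ms, R-S ∈ [2, 1000] ms — plus
D-R-S chains, ripple–spindle co-occurrence (SwR), D-SwR, and the fraction
of short/long ripples occurring alone vs in sequences.

**Phase locking.** Ripple peaks referenced to the Hilbert phase of the
0.5–4 Hz slow oscillation (positive peak = 0°, trough = 180°); locking is
assessed with the Rayleigh test (mean direction, resultant length R, p).

**Aperiodic spectra.** Welch PSDs (Hann, 4 s windows, 0.25 s overlap,
50 Hz notch, 0.25 Hz grid) are parameterized as

```
log10 P(f) = b − chi * log10 f + sum_k h_k exp(−(f − c_k)² / 2 s_k²)
```

offset `b` tracks overall activity; the exponent `chi` (negative slope) is
the standard E/I proxy — flatter slope, higher excitation/inhibition ratio.

**Sleep states.** Chronic hypnograms (1 s epochs, manually scored) are
ingested and summarized (TST, % per state, bouts > 4 s, transitions,
45-min bins). Anesthesia recordings are scored automatically: multitaper
band powers per 10 s epoch → PCA → 2-means; the cluster with the higher
mean PC1 (high slow-oscillation power and amplitude) is NonREM-like.

**Behavior.** Discrimination index `DI = (t_novel − t_familiar) / total`
per Object Space trial, with Stable (simple memory) and Overlapping
(cumulative memory) conditions.

## Worked example

```python
from sleeplfp.core import NREM
from sleeplfp.synth import SimConfig, EventSpec, generate_recording
from sleeplfp.preprocess import bandpass
from sleeplfp.detect import ripple_threshold, detect_ripples

cfg = SimConfig(
    duration=120.0, fs=2500.0, state_schedule=[(NREM, 120.0)],
    event_specs=[EventSpec(kind="RIPPLE", duration_ms=d)
                 for d in (60, 80, 120, 150)],
    seed=42,
)
bundle, truth = generate_recording(cfg)

filt = bandpass(bundle.channel("HPC"), bundle.fs, 100.0, 300.0)
threshold = ripple_threshold([filt], bundle.fs, sd_multiplier=5.0,
                             offset=5.0, min_nrem_s=0.0)
events = detect_ripples(filt, bundle.fs, threshold)

print(f"detection threshold: {threshold:.1f} uV")
for e in events:
    print(f"  {e.length_class:<5} ripple at {e.peak:7.3f} s, "
          f"{e.duration_ms:5.1f} ms, {e.amplitude:5.1f} uV, "
          f"{e.mean_frequency:5.1f} Hz")
```

prints

```
detection threshold: 51.4 uV
  SHORT ripple at   7.804 s,  74.0 ms, 111.2 uV, 150.7 Hz
  LONG  ripple at  20.020 s, 137.2 ms, 106.0 uV, 150.1 Hz
  LONG  ripple at  47.548 s, 108.8 ms, 110.8 uV, 150.7 Hz
  SHORT ripple at 104.700 s,  56.4 ms, 107.1 uV, 151.7 Hz
```

All four embedded ripples (two short, two long) are recovered: the
threshold is 5× the SD of the filtered NonREM trace plus the 5 µV offset;
durations are measured between half-threshold crossings, amplitudes are
envelope peaks, and mean frequencies sit at the 150 Hz carrier the
generator embedded.

A full session runs through one call (or the `sleeplfp run` CLI verb) and
writes events, coupling records, phase samples, spectra, aperiodic fits and
a reproducibility manifest:

```python
from sleeplfp.pipeline import PipelineConfig, run_session
run_session(PipelineConfig(regime="chronic", bundle_path="rec.dat",
                           hypnogram_path="hyp.csv", output_dir="out"))
```

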