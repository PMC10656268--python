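# Methods

This note documents the models, parameters and numerical choices behind
`sleeplfp`, and what the synthetic-data validation does and does not show
about real recordings.

## Signal model and preprocessing

Recordings are treated as multi-channel continuous voltage in µV with a
hippocampal CA1 channel (ripples), a prelimbic-cortex channel (slow
oscillations, delta waves, spindles) and three accelerometer axes. Two
regimes with fixed defaults:

| parameter | chronic | acute (urethane) |
|---|---|---|
| analysis rate | 2.5 kHz | 600 Hz |
| anti-alias cutoff | 1.25 kHz | 300 Hz |
| ripple band | 100–300 Hz | 90–200 Hz |
| ripple min duration | 20 ms | 50 ms |
| ripple closeness | 20 ms | 80 ms |
| threshold | 5×SD + 5 µV | 5×SD |
| epoch length | 1 s | 10 s |

All filters are 3rd-order Butterworth prototypes applied forward–backward
(`sosfiltfilt`), so they are zero-phase; the effective magnitude order is
doubled, and we quote the prototype order throughout. Artifact blanking
replaces suprathreshold samples (chronic: plus a 1 s buildup window; acute:
0.5 s buildup and 3.5 s washout around samples where the summed absolute
value of the two raw channels crosses threshold) with the clean-signal
mean, and is applied *after* band-pass filtering so blanking
discontinuities never ring through a filter. The chronic amplitude
threshold, chosen visually in practice, defaults to 8× the robust SD
(1.4826·MAD) of the bout; the replacement mean is computed from
below-threshold samples only, so the artifacts themselves do not bias it.
The acute regime discards the first 15 min (probe stabilisation). The
chronic threshold is per-session with a per-bout override, since nothing
in the recording model makes it bout-specific.

## Event detectors

**Ripples.** Detection thresholds the magnitude of the analytic signal
(Hilbert envelope) of the band-passed trace rather than the rectified
trace: the envelope rides on the voltage peaks and makes duration
estimates insensitive to carrier phase. The per-study-day threshold
averages per-trial-period values (5 × SD of the concatenated filtered
NonREM signal of that period) over all periods contributing more than
3 min of NonREM, then adds a 5 µV offset. Candidate suprathreshold runs
must last the regime's minimum duration; runs closer than the closeness
gap merge; edges grow outward to the half-threshold crossings (if a
blanked region intervenes, the event truncates at its edge). Peak time =
envelope maximum; amplitude = envelope peak; mean frequency = first
spectral moment of the event's periodogram. SHORT/LONG classification at
100 ms is definitional on the emitted duration. Quiet-wake detection adds
three vetoes within ±0.5 s of a candidate peak: smoothed accelerometer
resultant above mean + 2 SD of its sleep-period values (movement),
5–10 Hz power above 2× its NonREM median (locomotion theta), and the
amplitude-artifact flag. The veto references are robust to degenerate
inputs: an identically-zero theta reference disables that veto with a
warning rather than vetoing everything.

**Spindles.** The 9–20 Hz envelope is smoothed over 100 ms; thresholds are
envelope median + k·scaled-MAD with k_low = 2.5 and k_high = 5. A spindle
is a low-threshold run of 0.4–3.0 s containing at least one high-threshold
excursion; runs closer than 100 ms merge first. Median/MAD (rather than
mean/SD) center and scale were chosen because the spindles themselves
inflate the envelope's mean and SD — with mean/SD thresholds a session
with a realistic spindle density pushes its own high threshold above the
spindle envelope and detection collapses; robust statistics make the
thresholds a property of the background.

**Delta waves.** On the 1–6 Hz trace, a candidate is the segment between
an upward and the next downward zero-crossing, lasting 100–1000 ms, whose
positive peak exceeds 2 × SD and is followed, before the next upward
crossing, by a trough below −1.5 × SD — the LFP signature of a cortical
down-state. Peak = positive-peak time; start/end = flanking
zero-crossings.

All spindle/delta thresholds are explicit config defaults in the style of
the classic freely-moving-animal toolboxes and are meant to be tuned per
rat; they are conventions, not fitted constants.

## Coupling and phase

Pair motifs use inclusive peak-lag windows (D-S 100–1300 ms, D-R
50–400 ms, R-S 2–1000 ms); "between x and y" is read as closed on both
ends. All qualifying pairs are counted — one delta preceding two spindles
yields two D-S records — and the fraction-in-sequence statistics use set
membership, so multiplicity cannot inflate fractions. Co-occurrence holds
when a ripple lies fully inside a spindle or when either event's start or
end falls inside the other. D-R-S chains join D-R and R-S on the shared
ripple; D-SwR joins D-S with ripple-hosting spindles.

Slow-oscillation phase is the angle of the analytic signal of the
0.5–4 Hz-filtered cortical channel, mapped to [0°, 360°) with the
convention positive SO peak = 0°, trough = 180° (the range alone does not
fix a convention; this one is stated everywhere phases are reported).
Locking is tested with the Rayleigh test (pingouin), reporting circular
mean, resultant length R and p; fewer than 5 phases is an error rather
than a meaningless p-value.

## Spectra and aperiodic fit

PSDs are Welch estimates: Hann taper, 4 s windows, 0.25 s overlap, 50 Hz
notch (Q = 30), reported as log10 power on a 0–100 Hz grid in 0.25 Hz
steps (native to the 4 s window). The aperiodic parameterization models
log10 power as a line in log10 frequency plus Gaussian peaks in linear
frequency, fitted in three steps: (i) a robust line — an ordinary fit
followed by a refit on the points at or below it, which excludes peak
bins; (ii) Gaussians extracted from the residual largest-first while the
residual maximum is ≥ 0.05, widths constrained to 1–8 Hz, at most 6 peaks
(bounded for determinism), refined jointly by least squares; (iii) a final
line fit on the peak-subtracted spectrum. No "knee" term is fitted — over
1–100 Hz in these data a single power law is adequate and only offset and
exponent are interpreted. The fit grid excludes 45–55 Hz so the notch
cannot distort the line. Event-triggered spectra use 4 s windows centered
on ripple peaks — matching the 4 s baseline segments drawn at random
(seeded) from NonREM — averaged within SHORT/LONG/baseline classes per
region.

Interpretation: the offset tracks broadband activity; the exponent is the
E/I proxy (flatter slope = higher excitation/inhibition ratio).

## Sleep states

Chronic hypnograms are ingested, never computed — manual scoring stays
outside the pipeline. Architecture statistics: TST; % of TST per sleep
state; bouts as maximal runs with the duration distribution keeping only
bouts strictly longer than 4 s; transitions at every label change; binned
percentages over 45-min bins with a partial final bin normalized by its
own duration.

Anesthesia scoring: per 10 s epoch and region, multitaper band powers
(DPSS tapers, time–bandwidth 4, eigenvalue-weighted; 0–100 Hz in 0.5 Hz
steps) for slow oscillation (0.1–1 Hz), delta (1–3), theta (3–6), low beta
(10–20), low gamma (30–45), high gamma (55–80) and ripple (90–300) bands —
deliberately lower ranges than the natural-sleep literature because
urethane slows cortical activity — plus the theta/SO ratio and the epoch's
peak amplitude. Epochs whose amplitude deviates from the median by more
than 3 scaled MADs are artifacts (with MAD = 0 the strict inequality
flags any non-zero deviation and leaves identical amplitudes alone).
Features are z-scored before PCA since band powers span orders of
magnitude; components 1–2 are kept; PC1's sign is fixed so the summed
slow-oscillation-power loading is positive, making the labeling rule
orientation-stable; 2-means (10 restarts, seeded) splits the PC1–PC2
plane and the cluster with the higher mean PC1 — high SO power and
amplitude, the NonREM signature — is NonREM-like.

## Counts, normalization, behavior

Events are assigned to trial-period bins (four 45-min inter-trial rests,
then a 3 h post-trial rest divided into four 45-min bins) by their *peak*
time — the peak is the detector's anchor. Normalized counts divide each
kind's per-bin counts by that kind's mean over the bins, so frequent
(delta, NonREM ripple) and rare (spindle, quiet-wake ripple) event types
share a scale; the normalization scope is the event set passed in (one
session by default; pool sessions of an animal × treatment before calling
to widen it). Rates divide by the NonREM minutes in the bin. The
discrimination index is (novel − familiar)/total exploration; the
"animal showed memory in vehicle" inclusion rule is emitted as a boolean
column and never applied silently.

## Synthetic-data generator

The generator is the test bench: it produces recordings in which every
quantity the pipeline later estimates is known exactly.

* **Background**: spectral shaping of white noise — each rFFT bin gets an
  independent complex-Gaussian amplitude with expected power
  `10^offset / f^chi` — so the log-log periodogram slope is −chi in
  expectation and slope/offset recovery is exact up to sampling error.
  Defaults chi = 1.5, offset = 3.0 log10(µV²/Hz) at 1 Hz, which give a
  broadband SD near 45 µV and a 100–300 Hz band SD near 10 µV at 2.5 kHz —
  the scale of rat CA1 LFP.
* **State structure**: NonREM adds a slow oscillation on the cortical
  channel (150 µV; 1 Hz natural, 0.7 Hz anesthesia-like), REM adds theta
  on the hippocampal channel (100 µV; 7 Hz natural, 4.5 Hz
  anesthesia-like — the slowed frequencies mirror urethane's effect and
  fall inside the classifier's lowered bands). Accelerometer variance is
  elevated only in wake and artifact segments.
* **Events**: sinusoids at the event's center frequency under a tapered
  cosine (Tukey, α = 0.25) envelope whose flat top keeps the
  half-threshold width close to the nominal duration, so duration-based
  ground-truth classes survive detection (a fully tapered Hann envelope
  would shrink measured durations to ~⅔ of nominal and scramble the
  SHORT/LONG boundary); a Hann envelope remains available. Default event
  amplitude is 10× the background SD in the event's own band. Delta
  events start on the positive half-cycle so one cycle reads
  peak-then-trough.
* **Coupling and phase**: coupled pairs realize requested peak lags
  uniformly within ±jitter; phase-locked ripples draw von Mises phases
  around the target and are placed at times where the cortical SO
  (present throughout in that mode) attains the drawn phase.
* **Determinism**: one seeded generator, draws in a fixed documented
  order; identical configs give bit-identical bundles.

What passing tests show — and what they do not: the generator produces
stationary 1/f backgrounds with noise-free event archetypes at controlled
amplitudes. Real recordings add non-stationarity, movement and chewing
artifacts, electrode drift, overlapping oscillations and amplitude
distributions the generator does not model; validation here establishes
correctness of the *algorithms* (thresholds, windows, bookkeeping,
estimators) and their sensitivity at a stated SNR (events ≥ 8× band SD),
not field sensitivity/specificity on rat data. Absolute detector
sensitivity is therefore characterized, not matched to any cohort.

## Validation problem sizes

The acceptance checks run a 30-min, 2.5 kHz session with 200 ripples for
detector fidelity; 100 random event streams (up to 200 events each) for
the coupling oracles; 120 s backgrounds × 4 exponents × 10 seeds for
aperiodic recovery; a 20-minute alternating-state anesthesia recording for
the classifier; and 100 phase-locked ripples for the phase analysis.
These sizes keep the full validation under a minute on one CPU while
leaving sampling error well inside the stated tolerances.

## Known limitations

* Spindle/delta thresholds are conventions with per-rat tuning expected;
  they are not derived from data.
* The aperiodic fit has no knee; spectra that flatten below ~1 Hz or bend
  above ~100 Hz need a different fit range.
* The anesthesia classifier assumes exactly two occupied states; recordings
  dominated by one state can split it into two clusters.
* Event mean frequency (spectral first moment) is biased toward the band
  center for very short events (few carrier cycles).
* Quiet-wake veto thresholds assume the accelerometer scale is constant
  within a session.
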