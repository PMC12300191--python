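# Methods

## Signal model and assumptions

The pipeline assumes a PPG signal whose in-band (0.5–5 Hz) spectrum is a
superposition of a cardiac component at the instantaneous heart-rate
frequency (plus a weaker second harmonic), periodic motion-artifact
components at the step cadence and its harmonics, slow baseline wander
(< 0.5 Hz), and broadband noise. The key identifying assumption is that
motion-artifact frequencies — and only those — also appear as dominant
peaks in the 3-axis accelerometer spectra, so the accelerometer can veto
PPG spectral peaks without any model of the artifact's amplitude or phase.
Heart rate is assumed to lie in 30–300 bpm (0.5–5 Hz) and to change slowly
relative to the 2 s estimate cadence; the tracking stage leans entirely on
that smoothness, not on any physiological dynamics model.

## Preprocessing

Outliers are samples that are negative or exceed `mu+ + 3*sigma+`, where
the statistics are taken over the strictly positive samples. Two choices
here were genuinely open and are worth recording:

* the statistics are computed over the **whole channel** passed in, not per
  sliding window — the rule references "a specified PPG signal", and a
  session-level threshold is stabler than a 8 s one;
* `sigma+` uses the population (n-denominator) convention; configurable via
  `detect_outliers(..., ddof=1)`.

Repair is linear interpolation between the nearest valid neighbours, with
constant extension at the channel ends. The 0.5–5 Hz 5th-order Butterworth
bandpass is applied **zero-phase** (forward–backward, reflective padding of
3× the effective order), trading the unspecified causal alternative for
undistorted pulse timing; the effective magnitude response is consequently
10th-order. Resampling is two-step: samples are reassigned to a uniform
axis spanning the original timestamps (absorbing device jitter), then
cubic-interpolated onto the target grid — exact for polynomials up to
degree 3. The median (k=7) + moving-average (w=3) smoothing replicates edge
values, which is the only edge policy that passes constants through
unchanged; it is applied per analysis window, after the session-level
stages, following the narrative order of the processing chain.
Accelerometer channels are signed, so the positivity-based outlier rule is
not applied to them; they are resampled only.

## Spectral stage

Welch parameters are not dictated by the method and were fixed as: Hann
segments of `min(256, N)` samples, 50 % overlap, FFT zero-padded to the
next power of two giving a grid spacing ≤ 0.01 Hz. The grid density is what
makes the masking rules meaningful: the ±0.1 Hz removal band spans ≥ 10
bins and the 5 %-relative plateau comparison operates on a smoothly
interpolated curve. A "peak" is a bin strictly greater than both
neighbours; band-edge bins cannot be peaks; power ties break toward the
lower frequency (the conservative, lower-HR choice). Candidate
deduplication is same-grid-bin equality.

The three masking rules are applied in order: (1) ±0.1 Hz around each
candidate; (2) around each PPG local maximum removed by (1), contiguous
bins whose power lies within 5 % (relative, either side) of that peak's
power, walking outward until the first failing bin; (3) when the candidate
set is non-empty, everything above `1.05 * max(F)`. An empty candidate set
disables masking. Rule (3) deliberately follows the stated form even though
it can remove a true cardiac peak lying above the cadence band; no
harmonic disambiguation beyond these rules is attempted. Note that rule (3)
makes masking non-monotone in the candidate set: adding a candidate that
raises `max(F)` relaxes the high cut.

A window with no surviving valid peak yields a **missing** estimate rather
than an error; downstream interpolation fills it.

## SAB-HRT tracking

Blocks are 20 consecutive estimates (40 s), non-overlapping; streaming
ingestion reduces to this batching. Grouping is a single sequential pass;
"most recently updated" means the group whose last member has the greatest
sequence index, which is unique by construction. Missing estimates are
skipped during traversal and neither create nor break chains. Open details
of the tie loop were resolved as: extension is **forward** in time by 10
estimates (20 s), capped at 3 extensions or the end of the stream, with a
persistent tie falling back to the most recently updated of the tied
largest groups. A terminal partial block is processed when ≥ 10 estimates
remain, else dropped. Grid points between blocks are bridged linearly so
the output trace is gap-free. Output smoothing is a centred moving average
(30 s default, 15 points on the 2 s grid; 10 s is the documented light
variant) with symmetric window shrinkage at the ends, which preserves the
trace span and constants.

## Synthetic sessions

The generator emulates exactly the spectral structure the pipeline
consumes: cardiac tone + second harmonic, a cadence-locked tone shared
between PPG and all accelerometer axes (axis phase offsets 0, 2π/3, 4π/3
so the axes are distinct but cadence-locked), accelerometer second harmonic
at half amplitude, sinusoidal baseline wander, white Gaussian noise,
negative dropout spikes, and a positive DC offset so the raw PPG is
positive-valued. Phases come from trapezoidal integration of the
instantaneous frequency trajectories, so time-varying HR and cadence stay
phase-continuous. Defaults are the hardest illustrative condition: 5 min at
PPG 182 Hz / accel 52 Hz, HR 112.8 bpm, cadence 2.8 Hz, artifact amplitude
3× cardiac, noise sd 0.2 (≈ 11 dB wideband against the unit cardiac
amplitude), wander 0.5 at 0.25 Hz, 1 % outliers.

What the generator does **not** model: realistic pulse morphology (dicrotic
notch, beat-to-beat variability), non-stationary artifact spectra (gait
changes within a window), sensor saturation, or cross-axis coupling beyond
a shared cadence. Passing tests therefore demonstrate the algorithmic
contracts and spectral behaviour, not field accuracy on real recordings —
the public benchmark datasets exist for that and need only the CSV column
mapping described in the README.

One measured consequence of the generator + masking rules worth knowing:
with cadence 2.8 Hz the artifact's second harmonic (5.6 Hz) falls outside
the analysis band, so each accelerometer axis's *second* PSD peak is a
noise local maximum at a random in-band frequency. In roughly a tenth of
windows such a peak lands within ±0.1 Hz of the cardiac frequency and the
masking (faithfully — the candidate rule has no power threshold) removes
the cardiac peak; the tracking stage then repairs those windows, which is
why the per-window cardiac hit rate sits near 90 % while the end-to-end
MAE stays below 0.1 bpm.

## Numerical choices and problem sizes

Tolerances: candidate/±0.1 Hz and plateau comparisons carry a 1e-12
epsilon against floating-point boundary ties; HR readout is rounded to
0.1 bpm; cubic-resampling identity holds to 1e-9 on polynomial signals.
Evaluation matches reference points to the output grid by nearest
timestamp within 1 s (half the shift) and reports MAE with the SD of the
absolute errors. Window timestamps are anchored at the window **start**
throughout (estimates, references, output grid), and channel duration is
`times[-1] - times[0]`.

Tests and the acceptance script use 5-minute single sessions (≈ 150
windows) and 1000-block grouping sweeps; the full suite runs in a few
seconds, and each end-to-end session costs well under a second on one CPU.

## Known limitations

* Rule (3) can suppress a true HR above the cadence band (e.g. sprinting
  with a low arm-swing cadence); the method offers no recourse by design.
* The one-size-fits-all Welch segment length (256 samples) gives ~0.15 Hz
  resolution at 39 Hz; two tones closer than that merge, and HR within
  0.1 Hz of a true cadence line is unrecoverable for that window.
* The 16 s window variant for very noisy data is selected by configuration,
  never auto-detected.
* No beat-by-beat analysis: the output is a 2 s-grid spectral HR trace, not
  an HRV-capable inter-beat series.
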