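# pulsetrack

Motion-robust heart-rate estimation from wearable photoplethysmography
(PPG), for engineers and researchers working with smart-ring or wristband
recordings. Wrist and finger PPG during walking or running is dominated by
periodic motion artifacts at the step cadence, which often carry more
spectral power than the cardiac component itself. `pulsetrack` turns a
single-channel PPG stream plus 3-axis accelerometer data into a continuous
heart-rate trace using one fixed parameter set — no per-subject or
per-session calibration.

## Method

Per 8 s analysis window (2 s shift), after outlier repair, 0.5–5 Hz
5th-order Butterworth bandpass, cubic resampling to a common rate, and
median (k=7) + moving-average (w=3) smoothing:

1. **Welch PSDs** of the PPG window and the three accelerometer axes on a
   dense common frequency grid over the 0.5–5 Hz band.
2. **Candidate motion frequencies** — the two highest PSD peaks per
   accelerometer axis, deduplicated:
   `F = {f_1x, f_2x, f_1y, f_2y, f_1z, f_2z}`, |F| ≤ 6.
3. **Masking** of the PPG spectrum: bins within ±0.1 Hz of any f ∈ F are
   invalid; contiguous bins within 5 % of a removed PPG peak's power are
   invalidated too; all frequencies above 1.05·max(F) are invalid.
4. **Readout** — `HR = 60 · f_peak` (bpm) from the highest-power valid
   peak; a fully masked window yields a missing estimate.
5. **SAB-HRT tracking** — per block of 20 estimates (40 s), chain values
   into *stability groups* (consecutive members ≤ 10 bpm apart, each value
   joining the most recently updated qualifying group), keep the largest
   group, extend the block by 20 s on size ties, interpolate the kept
   points onto the 2 s grid, and smooth with a centred 30 s moving average
   (reducible to 10 s).

A synthetic session generator with known instantaneous HR and cadence, and
an MAE evaluation harness, make every stage testable without real
recordings.

## Worked example

A 5-minute synthetic session at the smart-ring rates (PPG 182 Hz,
accelerometer 52 Hz), heart rate 112.8 bpm (1.88 Hz), cadence 2.8 Hz, and a
motion artifact three times the cardiac amplitude — so the strongest PPG
spectral peak is the artifact, not the heart:

```python
from pulsetrack import (PipelineConfig, SimulationConfig, align_and_mae,
                        run_pipeline, simulate)

cfg = SimulationConfig(seed=1)            # 5 min, HR 112.8 bpm, cadence 2.8 Hz,
session = simulate(cfg)                   # motion artifact 3x the cardiac amplitude
trace = run_pipeline(session.ppg, *session.acc_channels,
                     PipelineConfig(target_rate_hz=39.0))
print(f"first HR points (bpm): {trace.hr[:3].round(1)} at t = {trace.t[:3]} s")
print(align_and_mae(trace, session.truth))
```

prints

```
first HR points (bpm): [112.5 112.7 112.6] at t = [0. 2. 4.] s
MAE 0.08 ± 0.05 bpm (n=140)
```

i.e. the accelerometer-guided masking removed the 2.8 Hz artifact peak and
the tracked output sits within a tenth of a bpm of the true 112.8 bpm,
despite the artifact outweighing the cardiac component 3:1 in amplitude.

## Command line

```bash
pulsetrack simulate --config sim.yaml --out-dir session/
pulsetrack estimate --ppg session/ppg.csv --acc-x session/acc_x.csv \
    --acc-y session/acc_y.csv --acc-z session/acc_z.csv \
    --ppg-rate 182 --acc-rate 52 --out hr.csv
pulsetrack evaluate --estimate hr.csv --reference session/truth.csv
```

Signals are CSV with columns `time_s,value`; HR output is
`time_s,hr_bpm`. Pipeline parameters come from a YAML file (see
`pulsetrack.config.PipelineConfig` for the layout and defaults).

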