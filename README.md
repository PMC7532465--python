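# bcgsleep

Contactless sleep-apnea screening and vital-sign monitoring from a
bed-embedded ballistocardiogram (BCG) pressure sensor.

A pressure mat under the mattress records, at 50 Hz, the force the body
exerts on the bed: a large respiratory oscillation, a small cardiac
(cardioballistic) beat train riding on it, gross body movements, and
near-flat stretches when the bed is empty. `bcgsleep` implements a full
analysis pipeline for such single-channel recordings, aimed at people
building or evaluating unobtrusive sleep-monitoring systems against
polysomnography (PSG):

1. **Artifact suppression** — 30-s windows with 50% overlap are labeled
   *out-of-bed* when the window SD falls below 5 mV, and *motion
   artifact* when it exceeds 4× the median absolute deviation (MAD) of
   the whole-night SD array; *signal coverage* is the fraction of
   recording time that survives.
2. **Vital signs** — per-window heart rate from the level-4 smooth of an
   undecimated Daubechies-4 wavelet decomposition (detrended by a 2-s
   moving average), and respiratory rate from a zero-phase 0.1–0.8 Hz
   band-pass; each rate is `60 / median(inter-peak interval)`.
   References: Pan–Tompkins QRS detection on the ECG and peak detection
   on the thoracic-effort belt.
3. **Apnea detection** — an unsupervised, per-recording adaptive
   threshold: the average absolute deviations (AAD) of 30-s respiratory
   windows are histogrammed (100 equal-width bins), bins are ranked by
   count, and the center of the k-th ranked bin (k = 6) becomes the
   threshold *T*. A sliding 60-s window with subslice AADs
   a₁ ≤ a₂ ≤ a₃ is flagged apneic when `a₃ − a₂ > f·T` (f = 0.45).
   Motion artifacts are deliberately left in: apneic episodes terminate
   in exactly the movement bursts the rule keys on.
4. **Calibration** — leave-one-out cross-validated grid search over
   k ∈ 2..16 and f ∈ 0.20..0.95 (step 0.05), scored by balanced
   accuracy = (sensitivity + specificity)/2.
5. **Evaluation** — windowed confusion metrics with a two-tailed
   association test, and device agreement via NMAE, NRMSE, MAPE,
   Bland-Altman limits of agreement (mean ± 1.96 SD) and Pearson *r*.
   AHI (events per hour of sleep) with the clinical severity classes
   <5 / 5–15 / 15–30 / ≥30.

Because clinical BCG recordings are not publicly available, the package
ships a first-class synthetic generator (`bcgsleep.simulate`) that
produces seeded 50 Hz recordings with aligned ECG/effort references and
ground-truth beats, breaths, apneic events, motion bursts and
out-of-bed stretches.

## Worked example

```python
from bcgsleep import (SimulationConfig, confusion_metrics, detect_events,
                      events_to_windows, extract_respiratory_component,
                      fit_threshold, simulate_recording)

cfg = SimulationConfig.apnea_oracle_regime(duration_s=7200.0, seed=1)
bcg, ecg, effort, truth = simulate_recording(cfg)

resp = bcg.copy_with(samples=extract_respiratory_component(bcg.samples, bcg.fs))
model = fit_threshold(resp)            # adaptive per-recording threshold
series = detect_events(resp, model)    # 60-s windows, f = 0.45
reference = events_to_windows(truth.apnea_events, series.grid)
cm = confusion_metrics(series.predicted, reference)
```

The annotated version of this script, `examples/04_apnea_detection.py`,
prints:

```
AAD threshold T = 117.8 mV
windows: 239  predicted apneic: 87  reference apneic: 82
sensitivity 0.963  specificity 0.949  accuracy 0.954  (p = 4.9e-44)
```

The fitted threshold sits in the normal-breathing bulk of the
AAD histogram, and under idealised conditions — stable respiratory
amplitude, 85% amplitude drop during events, strong arousal bursts —
the subslice rule recovers over 95% of apneic windows while flagging
few normal ones. Under realistic overnight amplitude drift the same
defaults give window-level sensitivity/specificity around 0.6–0.8
(see `scripts/acceptance.py` output), which is the regime clinical
deployments of this sensor class actually report.

The `examples/` directory holds one short script per capability:
simulation, artifact labeling, vital-sign agreement, apnea detection
and parameter calibration.

## Command line

A thin CLI wraps the library:

```bash
bcgsleep simulate --subjects 4 --duration 3600 --seed 1 --out data/
bcgsleep preprocess  --signal data/S01/bcg.csv --out labels.csv
bcgsleep vitals      --signal data/S01/bcg.csv --out vitals.csv
bcgsleep detect-apnea --signal data/S01/bcg.csv --events data/S01/events.csv --out apnea
bcgsleep calibrate   --manifest cohort.csv --out calib
bcgsleep evaluate    --bcg data/S01/bcg.csv --ecg data/S01/ecg.csv \
                     --effort data/S01/effort.csv --out report.json
bcgsleep run-all     --subjects 4 --duration 1800 --seed 1 --out run/
```

All file formats are plain CSV (see `bcgsleep.io`); identical config
and seed reproduce outputs byte-identically.

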