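# Methods

## Signal model and what the pipeline assumes

The input is a single-channel pressure signal from a bed-embedded
sensor, sampled at 50 Hz, in millivolts. Its content is modeled as the
sum of (i) a respiratory oscillation at 6–40 breaths/min whose
amplitude dominates everything else, (ii) a cardiac beat train at
40–180 beats/min roughly one third to one tenth of the respiratory
amplitude, (iii) broadband sensor noise, (iv) sporadic gross body
movements whose amplitude dwarfs respiration, and (v) near-zero
stretches when nobody is on the mattress. All stages operate on fixed
overlapping window grids (window w, hop w/2) with trailing partial
windows dropped, so per-window statistics stay comparable.

## Artifact suppression (SD–MAD rule)

For every 30-s window the sample SD (n−1 denominator; configurable) is
computed. A window is *out-of-bed* if SD < 5 mV; otherwise it is a
*motion artifact* if SD > m·MAD, where MAD is the unscaled median
absolute deviation of the whole-recording SD array and m = 4 by
default. The out-of-bed test runs first: a flat window can never be a
motion artifact. If the SD array is degenerate (MAD = 0, all windows
identical) nothing is flagged as motion and a warning is emitted — by
the rule's own logic an all-identical array contains no outliers.
Coverage merges suppressed windows into intervals before measuring
duration, so overlapping windows are not double-counted.

A consequence worth stating explicitly: the rule only behaves like a
motion detector when the SD distribution has a wide bulk (MAD of order
median/4). On real overnight recordings this holds because breathing
depth and sensor coupling drift by large factors; the synthetic
generator reproduces it with a lognormal amplitude drift (below).
With m = 4 roughly the top fifth of windows is suppressed, matching
the 51–88% coverages typical of this sensor class.

## Heart rate and respiratory rate

The cardiac component of a window is the level-4 approximation
("smooth") of a shift-invariant (undecimated) Daubechies-4 wavelet
decomposition — a ≈0–1.56 Hz low-pass at 50 Hz that turns each beat
complex into a single hump — minus a 2-s centered moving average that
suppresses most of the respiratory baseline. The respiratory component
is a zero-phase 4th-order Butterworth band-pass of 0.1–0.8 Hz with
generous reflect padding (10 s), which also removes the slow nonlinear
trend. Wavelet family, level, detrending span and band edges are all
keyword arguments.

Rates use `scipy.signal.find_peaks` with a minimum separation of
60/180 s (HR) or 60/40 s (RR) and a prominence floor of k·MAD of the
component (k = 0.02 by default — the floor only guards degenerate
near-flat windows; the separation constraint and the low-pass character
of the components do the real work). The window rate is 60 divided by
the *median* inter-peak interval, which tolerates isolated missed or
spurious peaks; windows with fewer than 3 peaks, rates outside
40–180 bpm / 6–40 breaths/min, or a multimodal interval distribution
(75th/25th percentile ratio above 1.5 — the signature of runs of
missed or split peaks, whose median would be biased rather than merely
noisy) are marked invalid rather than clipped.
Because the prominence floor is MAD-relative, estimates are invariant
to global amplitude scaling.

References: R-peak times from a Pan–Tompkins detector (5–15 Hz
band-pass, derivative, squaring, 150-ms integration, dual adaptive
thresholds with missed-beat search-back; on search-back failure the
signal-peak running estimate is halved so the thresholds recover after
large artifacts), and effort-belt peaks through the same rate logic.

## Apnea detection (adaptive AAD histogram)

Fitting, per recording and per patient, on the respiratory component
*without* artifact removal: AAD (mean absolute deviation about the
window mean; median-centered variant available) of 30-s windows at 50%
overlap; equal-width histogram with 100 bins over [0, max(AAD)]; bins
ranked by count descending with stable ties (lower AAD first, so ties
pick the more conservative threshold); threshold T = center of the
k-th ranked bin, k = 6. The top-ranked bins are the normal-breathing
bulk; the 6th sits at its edge.

Detection: 60-s windows at 50% overlap (30-s variant available), each
split into three contiguous subslices whose AADs are sorted ascending
a₁ ≤ a₂ ≤ a₃; the window is apneic iff a₃ − a₂ > f·T with f = 0.45.
The statistic fires when exactly one subslice is elevated (a movement
burst or resumed breathing) or when two subslices are quiet against one
normal — i.e. it detects the *contrast* an apneic episode creates, not
the quiet spell itself.

Reference labeling: a grid window counts as apneic when a scored event
overlaps it by more than 10 s — the clinical minimum event duration.
Any-overlap labeling (`min_overlap_s=0`) is available, but it scores
windows brushed by an event tail shorter than any scorable apnea as
positives; such windows produce the subslice pattern
(quiet-ish, normal, normal), whose top gap is identically zero, so no
threshold can ever recover them. With any-overlap labeling the rule's
window sensitivity has a geometric ceiling near 0.8 regardless of the
data; the 10-s floor makes the labeling consistent with what the
statistic can express.

## Parameter calibration

Leave-one-out over subjects: for each held-out subject every
(k, f) cell with k ∈ 2..16 and f ∈ 0.20..0.95 step 0.05 is scored on
the remaining subjects (threshold refitted per recording), recording
unweighted means of sensitivity, specificity and accuracy; the overall
cell score is mean balanced accuracy across iterations. Undefined
metrics (single-class references) propagate as NaN and are excluded by
nan-means. Because the subslice spread and the ranked histogram do not
depend on (k, f), they are precomputed once per subject and each cell
reduces to one vectorised comparison; the full 15×16 grid on six
one-hour subjects takes seconds.

Two k-selection rules are exposed: `knee` — the k with the largest
absolute change in mean sensitivity to the next rank (sensitivity falls
and specificity rises in k; the knee marks the crossover) — and
`argmax` of mean overall balanced accuracy. Ties break toward smaller
k and smaller f.

## Agreement statistics

NMAE and NRMSE are MAE and RMSE of (estimate − reference) divided by
the mean of the reference series, ×100; this normalisation makes NMAE
coincide with MAPE when the reference is constant, which is the
behaviour observed in published per-patient tables for this sensor
class (NMAE ≈ MAPE to two decimals). The normaliser is configurable.
Limits of agreement are mean difference ± 1.96 sample SD (n−1).
Pairs are restricted to windows valid in both series. The windowed
confusion table's P value is a two-tailed chi-square test of
independence, replaced by Fisher's exact test when any expected cell is
below 5 — the association test is an interpretation, as the clinical
reports leave the test unnamed.

## Synthetic recordings: what they emulate and what they do not

The generator is the package's study population. Its defaults are the
study conditions; every number below is a deliberate choice.

* **Respiration**: per-cycle period jitter (Gaussian, truncated at ±20%
  of the mean period) around 15 breaths/min, amplitude 150 mV times a
  lognormal Ornstein–Uhlenbeck drift (σ = 0.6, correlation time 120 s).
  The wide drift is what makes the SD–MAD artifact rule behave as on
  real nights (coverage ≈ 65–85%); it also means the AAD histogram has
  a broad normal bulk.
* **Cardiac**: beat template = 0.35·(4 Hz Gabor oscillation) + a slower
  Gaussian J-wave hump (σ = 0.15 s), peak 50 mV, at 65 ± 2 bpm. The
  hump carries the sub-1.5 Hz energy that survives the level-4 smooth;
  a pure high-frequency oscillation would leave the smooth almost
  beat-free and no wavelet HR estimator could work on it.
* **Apneic episodes**: respiratory amplitude ×0.15 during the event
  (an 85% drop); each scored event ends with a movement burst occupying
  its final seconds — the arousal that terminates the apnea — modeled
  as low-pass (≤1.5 Hz) noise with a crescendo/decay envelope. The
  low-frequency character matters: body movements shift the pressure
  baseline, so their power lies inside the respiratory band where the
  detector looks; white-noise bursts would lose ~98% of their power to
  the band-pass and be undetectable. Events are placed uniformly at
  random with a minimum onset-to-onset spacing (30 s by default), with
  the event count set by the target AHI; onset-to-onset spacing (rather
  than end-to-onset) is what makes very severe nights (AHI > 90)
  representable at all.
* **Motion bursts and out-of-bed**: the same burst model at a
  configured rate, and near-zero noise (SD 1 mV) segments.
* **References**: the ECG channel is narrow Gaussian R-pulses at the
  true beat times; the effort channel *is* the respiratory component.

`SimulationConfig.apnea_oracle_regime()` is a documented preset for the
regime in which the subslice rule is expected to work: stable amplitude
(σ = 0.10, so clean and apneic AAD distributions separate by ≥5×),
AHI 20 with ≥60-s spacing (windows contain at most one event — two
elevated subslices cancel in a₃ − a₂), pauses of 10–14 s followed by
12-s strong bursts, no spontaneous motion, 4 h. Across seeds this
yields window sensitivity 0.90–0.96 and specificity 0.92–0.96 at the
default operating point. The same defaults on the realistic default
conditions give roughly 0.6–0.8 — passing the idealised test
demonstrates the mechanism, not field performance.

What the generator does not emulate: beat-morphology variability across
subjects and postures, snoring and flow-limitation signatures,
position-dependent coupling changes, central vs obstructive waveform
differences (event types are labels only), desaturation, and any
coupling between apnea severity and cardiac function. Results on
synthetic data therefore validate the *algorithms* — thresholds,
windowing, statistics, selection — not clinical accuracy.

## Numerical choices and degenerate inputs

Stable tie-breaks everywhere (lower histogram bin, smaller k, smaller
f, first window). Histogram bin representative = bin center. Sample
SDs with n−1; MAD unscaled. Rates from medians, never means. Empty
windows, all-constant signals, unfitted models, sub-minimum cohorts and
zero sleep time raise informative errors; too-few-peaks windows become
NaN with a false valid mask instead. All simulation randomness flows
from one integer seed through `numpy.random.default_rng` /
`SeedSequence`, and identical configurations reproduce outputs
bit-identically.

## Problem sizes used by the shipped experiments

The test suite and `scripts/acceptance.py` use six-subject cohorts of
30–60 min recordings for calibration and agreement studies, a 4-h
recording for the detection-power experiment, and three 10-min
recordings for vital-sign recovery — sizes at which every reported
statistic is stable across seeds while the whole suite runs in well
under ten minutes on one CPU.

## Known limitations

The a₃ − a₂ statistic is blind to windows where an event contributes
only a single partially-quiet subslice, and two simultaneous elevated
subslices cancel; its window-level sensitivity is therefore bounded
well below 1 outside single-event geometries. The threshold T inherits
the histogram's bin quantisation: when rare huge bursts stretch the
[0, max] range, T can jump between adjacent bins across otherwise
similar recordings. HR estimation degrades in high-amplitude windows
where the respiratory residual slope approaches the beat-hump slope —
which is also where the artifact rule tends to suppress windows first.
The Pan–Tompkins reference at 50 Hz localises R-peaks to ±20 ms at
best, bounding achievable HR agreement.
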