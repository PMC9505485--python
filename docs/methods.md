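# Methods

## The analysis

The pipeline estimates cognitive workload (three levels: baseline driving;
driving + dialogue; driving + dialogue + braking, the last labelled with a
stimulus-onset asynchrony from {0, 0.5, 1} s) from three physiological
modalities, then asks two questions: do the extracted features separate the
levels statistically, and how well do standard classifiers distinguish level
pairs from single modalities or fused representations?

Conventions: time in seconds, 0-based sample indexing, half-open analysis
windows `[onset, onset + duration)`. Pupil and EEG features use 2.5 s
post-onset windows with a 1 s pre-onset baseline; cardiovascular features
use 30 s windows.

## Preprocessing

**Pupil.** Samples outside [0.8, 10] mm (strict inequalities; values at the
bounds are kept) are treated as blink artifacts or implausible dilation and
linearly interpolated between the nearest valid neighbours; edge runs are
held at the nearest valid value. A zero-phase 5th-order Butterworth low-pass
at 10 Hz removes residual noise. Zero-phase (forward–backward) filtering is
used throughout the package: the analysis is offline and group delay would
shift feature windows. The filtered trace is clamped to the valid range so
edge ringing cannot reintroduce out-of-range samples; the interpolated
fraction is recorded per trial and drives the quality flag (> 50 %
interpolated ⇒ trial discarded).

**EEG.** Zero-phase 6th-order Butterworth band-pass 0.1–30 Hz (the 0.1 Hz
edge settles over ~10 s, so filtering uses the longest reflective padding a
2.5 s trial allows; residual edge transients are an accepted limitation of
short windows). FastICA (deflation, `exp` contrast) decomposes the 8
channels; a component is rejected as a blink when its time-course kurtosis
exceeds 5 **and** more than 60 % of its absolute mixing-weight mass lies on
the frontal (FC) channels. Rejection is automatic; a manual override list
exists for interactive use. If ICA does not converge the step is skipped
with a logged warning and a flag. Finally each channel is smoothed by a
Kalman (RTS) smoother under a local-level model; the signal-to-noise ratio
q is estimated per channel by maximizing the concentrated prediction-error
likelihood over log q (the observation variance concentrates out
analytically), with a diffuse initial level.

**Blood pressure.** The 20 Hz trace is linearly resampled to 250 Hz (the
subsequent filter removes interpolation artifacts) and low-passed (5th
order, 5 Hz, zero-phase). Beat detection: strict local extrema form
systolic (SP) / diastolic (DP) candidates; same-type runs collapse to the
most extreme candidate (ties → earlier); a DP→SP pair must satisfy
SP − DP ≥ 10 mmHg, otherwise the pair member with the smaller prominence is
deleted and alternation restored; finally SP-to-SP interbeat intervals must
lie in [500, 2000] ms (120 down to 30 bpm) — an SP whose preceding interval
fails the gate is dropped (the *later* one, preserving the already-validated
rhythm) and the sequence re-evaluated to a fixed point. The amplitude gate
runs before the interval gate.

## Features

* Pupil: PCPS per sample (baseline = mean over the 1 s pre-onset segment),
  APCPS = mean PCPS; classification uses either the full 500-sample PCPS
  series or the handcrafted [mean, sample variance] pair (the latter feeds
  feature-level fusion). PCPS is invariant to global diameter scaling.
* Gaze: I-DT fixation detection — a maximal run with x-range + y-range
  dispersion ≤ 0.01 screen units lasting ≥ 100 ms is one fixation (both
  thresholds configurable; no standard algorithm is canonical here, and
  I-DT is the simplest dispersion-based choice).
* EEG: band powers by Welch's method (non-overlapping 2 s rectangular
  segments, density scaling) for statistics, and a single 2.5 s rectangular
  periodogram for per-trial classification features; powers are trapezoid
  integrals of the one-sided PSD over δ/θ/α/β, so the four bands sum to the
  1–30 Hz total exactly and total power matches time-domain variance
  (Parseval). γ (> 30 Hz) is excluded, consistent with the band-pass edge.
* HRV/BPV: time-domain statistics use sample denominators (N−1); RMSSD and
  SV are root-mean-squares over successive differences; ARV the mean
  absolute successive difference; CV = SD/mean × 100. Spectral features:
  beat-indexed series are cubic-spline interpolated onto a uniform 4 Hz
  grid (Nyquist-safe for the 0.4 Hz band edge; the rate is a package
  choice), mean-removed (so VLF is not a DC artifact), and the one-sided
  FFT power summed over VLF (0, 0.04), LF [0.04, 0.15), HF [0.15, 0.4) Hz.
  LFnu = LF/(LF+HF)×100 and HFnu is its exact complement. With 30 s
  windows the VLF band resolves at most one FFT bin — a known resolution
  caveat of very-short-term variability. No zero-padding is applied.

## Statistics

One-way ANOVA and Tukey's HSD (studentized range on the pooled error;
Tukey–Kramer for unbalanced groups) compare the three levels per feature;
"significance level 0.95" is read as α = 0.05. Benjamini–Hochberg step-up
adjustment is applied to pairwise Welch-t p-values (the base test is a
package choice, configurable); the implementation is cross-checked in tests
against a brute-force step-up oracle.

## Classification protocol

Stratified 80/20 train/test split per repeat seed (the seed governs split,
CV folds, and model initialization; repeats re-draw the split). Classical
families are tuned by stratified 5-fold CV on the training set over their
grids (k ∈ [1,30]; NB event models gaussian/bernoulli/multinomial/
complement/categorical, the count models behind a min–max or discretizing
transform; 1–50 trees; linear/polynomial/RBF/sigmoid kernels), with ties
resolved toward the simpler candidate (smaller k, fewer trees, kernels in
the order listed); the winner is refit on all training data.
Standardization is fit inside each fold — never on validation or test rows;
a leakage-canary test enforces this.

The neural model is a fully connected ReLU network (three hidden layers +
linear output) trained with Adam and tuned on a fixed stratified validation
split (20 % of training) over a learning-rate × batch-size grid. Reference
widths per modality: EEG (1024, 512, 64), pupil series (256, 128, 128),
low-dimensional features (32, 16, 16); the benchmark defaults use the small
widths with 120 epochs and a 1-point grid so the full cross runs in minutes
on one core — all sizes, grids and epochs are parameters.

**Fusion.** Feature-level: row-aligned concatenation of the 2-d pupil and
32-d EEG features (34 columns). Data-level: two per-modality networks whose
last-hidden activations feed a third (32, 16, 16) network. Training is
stage-wise: the per-modality networks are fit on a stratified 60 % of the
training rows and the head on the embeddings of the remaining 40 % — a
network can memorize its own training rows, so embeddings of those rows
would make an uninformative modality look predictive and mislead the head;
the held-out share gives the head an honest view in the same coordinate
basis used at prediction time. The head carries a stiff L2 penalty
(α = 1.0) because it sees high-dimensional embeddings from few rows.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, with
ground truth sufficient to score every detector:

* **Pupil** (200 Hz — the binocular eye camera's per-eye rate): per-trial
  baseline diameter ~ N(4.0, 0.5²) mm; the trial dilation d (in %) is drawn
  per level from (0.24, 6.08), (5.75, 7.36), (8.85, 6.71) — the observed
  per-level APCPS distributions — and applied through a raised-cosine onset
  ramp normalized to unit mean so the noise-free trial-mean PCPS equals d
  exactly. Blinks are 150 ms dips to 0.3 mm at 8/min; additive noise
  0.02 mm.
* **ABP** (20 Hz): beat onsets from an IBI process with configurable mean
  (default 72 bpm at all levels — mean heart rate is not a workload marker
  here) and SD (40 ms at rest, 42.5–43 ms at task levels: the variability
  shift sits between levels 0 and 1, matching the observed direction), plus
  0.1 Hz and 0.25 Hz sinusoidal IBI modulation (LF amplitude 0.015 at rest,
  0.018 at task levels). The waveform is a raised-cosine upstroke to a
  systolic peak at a fixed 0.3 × mean-IBI latency (so SP-to-SP intervals
  reproduce the programmed IBI process exactly) with an exponential
  diastolic decay; any waveform with unique per-beat extrema would do — the
  contract is on the recorded SP/DP ground truth. Per-beat SP ~ N(120,
  σ_SP), DP ~ N(80, σ_DP) with mildly level-dependent SDs (diastolic
  variability grows with level) and SP − DP ≥ 20 mmHg. Generated IBIs are
  clipped to [0.52, 1.95] s, inside the detector's gate.
* **EEG** (500 Hz, 8 channels): unit-RMS 1/f background scaled to 4 µV plus
  two tone sources per band mixed into channels with random positive
  weights (volume conduction; this also gives ICA a true mixing model).
  Alpha/beta amplitudes are mildly elevated at task levels; magnitudes are
  free parameters since only directions are known, and they are chosen
  small — together with a per-trial lognormal band-amplitude factor
  (σ = 0.35, reflecting how strongly real band power fluctuates between
  trials) this keeps EEG a weak workload marker, far below the pupil, which
  is the regime the analysis is about. Tone frequencies sit on the 2.5 s
  trial's 0.4 Hz frequency grid so recorded band powers are exact (no
  leakage). Blink spikes: 200 ms sin² bumps of 150 µV with a fixed rank-1
  frontal-dominant spatial pattern, 8/min.
* **Gaze**: piecewise-constant fixation centers with exponential dwells
  (minimum 120 ms, mean 0.34/0.31/0.24 s by level with lognormal per-trial
  jitter σ = 0.25, so fixation count rises and duration falls with
  workload while the count's trial-to-trial SD stays realistic), saccadic
  jumps ≥ 0.1 screen units, tremor SD 0.001; programmed dwell lists
  override the draws for recovery tests.

What the generator does **not** emulate: subject-level covariance between
modalities, non-stationary drift, motion artifacts, EEG line noise,
measurement dropout other than blinks, and realistic arterial pulse
morphology (dicrotic notch, reflected waves). Passing tests therefore demonstrate the correctness and
calibration of the pipeline on data satisfying its assumptions, not
performance on real recordings — whose headline accuracies depend on
undeposited human data and are explicitly out of scope.

## Quality filtering and balancing

A trial is discarded when > 50 % of its pupil samples were interpolated,
its 30 s pressure window yields fewer than 10 accepted beats, or any EEG
channel exceeds 500 µV (saturation). The retained trials are subsampled
(seeded) to equal class counts; the filter decision and subsample are made
once and shared across modalities so rows stay aligned for fusion.

## Problem sizes and numerical choices

The test suite runs the full chain at reduced trial counts (5–15 per
level) and the acceptance script at the study size (116 per level); beat
detection is validated on 5-minute traces across 45–110 bpm. Filter edge
handling uses reflective padding up to 3000 samples. Degenerate inputs:
all-constant series return zero variability; groups with zero within-
variance and distinct means return F = ∞, p = 0; LFnu/HFnu are defined as
0 when LF + HF = 0. CV-tie rule and the IBI-gate drop-later policy are
stated above; both are deterministic.

## Known limitations

* The 0.1 Hz EEG high-pass on 2.5 s windows necessarily leaves edge
  transients; in-band fidelity is assessed on the central region.
* Stage-wise fusion training spends 40 % of training rows on the head, so
  data-level fusion gives up 1–3 accuracy points relative to an oracle
  end-to-end fit when one modality is uninformative.
* The MLP omits batch normalization and dropout; its capacity is
  controlled by L2 weight decay instead.
* Plug-in interface only (no implementations) for published time-series
  architectures applied as-is in the original study (EEGNet, MLSTM-FCN,
  InceptionTime).
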