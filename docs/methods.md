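# Methods

This note documents the models, parameters and numerical choices behind
`eegpref`, what the synthetic cohorts do and do not emulate, and the known
limitations of the protocol the package implements.

## The classification protocol

One trial is 70 s of 19-channel EEG (10–20 montage, 500 Hz) around the
onset of a cream application: 15 s before the trigger, 30 s of application,
25 s after.  The trial's 1–9 preference score labels it *negative* (1–4),
*positive* (8–9) or unusable (5–7).  The analysis chain is:

60 Hz band-stop → −15…55 s segment → Morlet spectrogram → 3 s/1 s-hop
windows over 0–30 s → four band means per channel → 5×5 scalp-layout images
→ 10×10 merged image → per-subject oversampling and baseline correction →
CNN classifiers → LOSO evaluation with a 7 s median filter on the predicted
label sequence.

### Morlet filter bank

Fixed cycle count C = 14 for all centre frequencies 1…120 Hz (1 Hz steps):
σ_f = 2f/C, σ_t = 1/(2π σ_f), so σ_t σ_f = 1/(2π) everywhere.  Wavelets are
unit-energy; power is linear (µV²) with no log transform — the baseline
correction is scale-normalising, so the power scale cancels.  The transform
is implemented as a frequency-domain filter bank (one FFT per trial, a
Gaussian multiply per centre frequency, and a folded inverse FFT that
returns the convolution exactly at the 0.05 s output grid).  The result
matches a direct sampled-wavelet convolution to ~1e−6 relative error and
MNE-Python's `tfr_array_morlet` (with the equivalent `n_cycles = C/2 = 7`)
up to its constant normalisation; both comparisons are tests.

Edge effects: the envelope extends ±3σ_t ≈ ±3.3 s at 1 Hz, the worst case,
so the 0–30 s analysis span sits well inside the valid region of the
−15…55 s segment.

### Feature images

Band bins are half-open on 1 Hz bin centres — alpha 7–14, beta 15–32,
low gamma 33–69, high gamma 70–120 — giving a disjoint partition of
7–120 Hz with boundary bins assigned upward; 1–6 Hz is not used.  The 5×5
layout places the 19 electrodes by scalp geometry and fills the six gaps
with the arithmetic mean of the listed neighbours (the layout matrix is a
fixed 25×19 linear map, so channel sums are conserved and fills are convex
combinations).  The 10×10 merged image tiles alpha/beta in the top
quadrants and low/high gamma in the bottom quadrants, in reading order; any
fixed order is information-equivalent for the networks, and the mapping is
recorded in `MergedFrame.band_quadrants`.

### Dataset assembly and baseline correction

Order of operations: label → exclude single-class subjects → balance per
subject by random oversampling with replacement (originals retained,
duplicates flagged) → baseline-correct per subject:

    f′ = (f − f̄_neg) / (f̄_pos − f̄_neg)

per grid cell and band, with class-conditional means computed over the
subject's balanced windows.  After correction each subject's negative and
positive class means are exactly 0 and 1 at every cell.  Cells where the
class means coincide within a relative tolerance of 1e−12 are degenerate;
the default policy raises, an opt-in policy zeroes them with a warning.

**Leakage caveat.**  The per-subject statistics use the subject's own class
labels even when that subject is the held-out test subject — faithful to
the protocol being reproduced, and flagged here deliberately.  The
consequence is measurable: on synthetic cohorts with *no* class effect at
all, LOSO test accuracy of the stacked CNN is ≈0.73 rather than 0.5,
because the correction anchors every subject's class means at 0/1 and a
classifier can learn that universal anchoring from the training subjects.
The corresponding chance-level acceptance check is intentionally left
failing rather than weakened; any accuracy obtained under this protocol
mixes genuine class signal with this anchoring effect.  Training itself is
strictly subject-disjoint and audited (a test/validation subject found in a
training set is a hard error).

### Classifiers

Seven architectures, all with 10 filters per convolution, stride-1 'same'
zero padding (even kernels pad one less before than after), ELU (α = 1),
one dropout layer before the head (rate 0.5, configurable — the rate is not
fixed by the protocol), and a dense 2-way softmax head.  Glorot-uniform
weights, zero biases.

* stacked merged input (10×10): kernels 2,2,3,3,3;
* single band (5×5): kernels 2,2,3 — one model per band;
* parallel bands: four weight-independent single-band trunks,
  channel-concatenated before the head;
* inception-like merged input: three modules, each with four 10-filter
  branches — 1×1→2×2, 1×1→3×3, 1×1→5×5, maxpool(3×3, stride 1)→1×1 —
  concatenated to 40 channels at 10×10 and passed through one ELU.  The
  published layer table lists the branch ingredients (bottleneck, pooling,
  2×2/3×3/5×5 kernels) and the 40×10×10 module-2 input but not the exact
  wiring; this wiring uses every listed kernel exactly once and reproduces
  the printed inter-module shape.

The engine is a small NumPy implementation (patch-matrix convolutions via a
compiled extraction kernel, BLAS matrix products, single precision,
channels-last internally).  All layer gradients are verified against
central finite differences in the test suite.

### Training and evaluation

Adam (lr 2·10⁻⁴, β₁ 0.9, β₂ 0.999, ε 1e−8), batch 128, shuffled every
epoch, cross-entropy, fixed epoch budget with no early stopping and no LR
schedule.  Validation accuracy and loss are computed once per epoch; only
the two running-best parameter sets (max validation accuracy, min
validation loss; ties → earliest epoch) are retained, which is
mathematically identical to storing every epoch and selecting afterwards.

LOSO uses every ordered (test, validation) pair: n(n−1) folds.  Test
predictions are median-filtered per trial over the window-ordered label
sequence (kernel 7 = 7 s at the 1 s hop; binary median = sliding majority;
replicate edge padding; never across trial boundaries).  When test windows
are oversampled duplicates, filtering runs on the unique window sequence
and duplicates inherit their window's filtered label.  Note that a sliding
majority can occasionally flip the overall majority of a sequence; it is a
local smoother, not a majority-preserving operator.  Metrics follow the
positive-class convention (sensitivity TP/(TP+FN), specificity
TN/(TN+FP)); a metric with an empty denominator is reported as undefined
and excluded from averages with a warning.  Aggregation: per-subject means
over that subject's folds, then unweighted mean ± sd (ddof 1) across
subjects, per architecture × criterion × filter state.

## The synthetic cohorts

Each trial is synthesised in the frequency domain:

* background: Gaussian 1/f^χ noise (χ = 1, level 18 µV²/Hz at 1 Hz,
  flattened below 1 Hz) — total signal sd ≈ 10 µV;
* alpha rhythm: Gaussian spectral bump at 10 Hz (σ 1.5 Hz, peak equal to
  the background at 10 Hz);
* mains: 60 Hz sinusoid, 5 µV, random phase per channel;
* class effect: positive-scored trials add band-limited noise in the
  effect band (default low gamma) on the effect channels (default F7, F8,
  T3, T4 — fronto-temporal), with power `effect_size` × the background band
  power, gated to the 0–30 s application window, so the expected band power
  is multiplied by 1 + effect_size;
* per-trial, per-channel log-normal amplitude factor (σ 0.2 on the log
  scale, i.e. band power typically varies by ±40–50% between trials).
  This term is essential: without between-trial power variability the
  class-conditional means that baseline correction divides by differ only
  by microscopic estimation noise and the corrected features of
  no-effect cells blow up by orders of magnitude, which real EEG (and the
  corrected distributions the protocol reports) does not show;
* per-subject, per-channel log-normal gain (σ 0.3) and DC offset
  (σ 5 µV) — the cross-subject domain shift that makes baseline correction
  consequential.

Scores: positive trials draw uniformly from {8, 9}, negative from {1…4},
mid trials from {5…7}; the default score model draws designations with
probabilities 0.5/0.35/0.15 and guarantees each subject both classes;
single-class subjects (for exclusion tests) are generated explicitly.
Seeding is hierarchical (`SeedSequence` spawn keys per subject and trial),
so cohorts are bit-identical regardless of generation order, and the
on-disk NPZ containers are byte-for-byte reproducible.

What the generator does **not** emulate: physiological artifacts (EMG, eye
blinks, motion), non-Gaussian microstructure, volume-conduction correlation
between channels, nonstationary rhythms, or realistic score psychology.
Passing tests therefore demonstrate that the pipeline recovers a known
band-power effect under realistic spectral and between-trial/-subject
variability — not that the published real-data accuracies are reproduced.

## Problem sizes used in the checked runs

The end-to-end checks run 8-subject, 8-trial cohorts with the stacked
merged-input CNN at 50 epochs, evaluating a deterministic stride subset of
the 56-fold LOSO schedule (28 folds for the effect cohort, 14 for the
no-effect cohort; every subject serves as test in both).  The
reproducibility check runs the 4-subject demo configuration (two
architectures, 20 epochs) twice and compares artifacts byte for byte.
Development runs of the full 56-fold schedule gave the same conclusions as
the subsets (effect cohort ≈ 0.78 mean filtered accuracy; no-effect cohort
≈ 0.73 — the leakage floor discussed above; seed 11).

## Known limitations

* The baseline-correction leakage described above is inherent to the
  protocol; a deployment-grade variant would need label-free per-subject
  normalisation for unseen subjects.
* The median filter is applied to hard labels; a score-median variant is
  not implemented.
* The oversampling duplicates windows rather than interpolating; balanced
  test-set metrics double-count minority windows (an `unbalanced_test` switch in fold evaluation
  drops the duplicates before tabulating).
* Training the full 7-architecture, 16-subject, 300-epoch protocol is
  CPU-days on this engine; the package is built to scale down honestly
  (fewer subjects/epochs/folds) rather than to reproduce that compute.
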