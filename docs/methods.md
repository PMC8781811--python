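# Methods

## Problem and overall procedure

Sleep apnea (SA) leaves a signature in the single-lead ECG: during apneic
episodes the RR interval lengthens and shortens cyclically (a bradycardia–
tachycardia oscillation with a period of tens of seconds) and the R-peak
amplitude is modulated by the intensified respiratory effort. `msapnea`
detects SA minute by minute from these two *derived* signals rather than
from the raw waveform, then aggregates per-minute decisions into a
per-recording apnea–hypopnea index (AHI) and diagnosis.

The pipeline is: FIR band-pass denoising → R-peak localization →
RR-interval and R-peak-amplitude series → uniform resampling → 60 s
segmentation → multi-scale 1-D residual classifier trained with a focal
loss → per-recording AHI.

## Signal model of the synthetic generator

The generator (`msapnea.synth`) emulates only what the pipeline consumes:

- **QRS morphology** — a fixed Ricker wavelet (~80 ms support) whose centre
  sample equals the configured amplitude. No P or T waves, no morphology
  variability between beats beyond amplitude.
- **RR process** — normal minutes draw RR ~ N(0.85 s, 0.04 s) plus a small
  respiratory sinus-arrhythmia sinusoid (0.02 s at 0.25 Hz). Apneic (AH)
  minutes add a sinusoid with period 45 s and amplitude 0.15 s — the
  cyclical variation characteristic of apneic episodes — and scale peak
  amplitudes by (1 ± 0.3) on the same cycle. AH minutes form one contiguous
  episode per record, as events cluster overnight.
- **Noise** — the three clinically dominant components, each with a
  physiologically plausible default relative to the 1 mV R peak: baseline
  wander 0.3 mV at 0.33 Hz (band 0.05–2 Hz), powerline 0.1 mV at 50 Hz,
  and white "EMG" noise with 0.05 mV standard deviation.
- **Quantization** — samples are rounded to a 16-bit ADC grid (200 adu/mV)
  so the WFDB round trip is bit-exact.

What the generator does **not** emulate: ectopic beats, atrial
fibrillation, electrode motion artefacts, morphology-based distinctions
between obstructive and central events, or hypopnea severity grades.
Passing tests on this data therefore demonstrate that the machinery —
filtering, detection, resampling, the network, the training loop, the AHI
arithmetic — is wired correctly and can recover a known apnea signature;
they do not certify clinical performance on recorded patients, which
depends on far messier signals than these.

## Preprocessing

- **Filter** — linear-phase FIR band-pass, 3–45 Hz, one second of taps
  (odd count), applied with a centred convolution so the group delay is
  compensated exactly and output length equals input length. The band
  removes baseline wander and powerline interference while keeping the QRS
  energy (mostly 5–25 Hz).
- **R-peak detection** — the Pan–Tompkins chain with Hamilton-style
  adaptation: derivative, squaring, 150 ms centred moving-window
  integration, adaptive signal/noise threshold (`noise + 0.25·(signal −
  noise)`, 1/8 exponential updates), 200 ms refractory period, and
  searchback over rejected candidates at half threshold when no beat has
  been accepted for 1.5× the running RR estimate. Peak indices are refined
  to the local maximum of the filtered ECG within ±50 ms; the amplitude is
  read there. A zero-variance signal yields an empty series, not an error.
- **Derived series** — RR point *i* sits at abscissa *tᵢ* with ordinate
  *tᵢ − tᵢ₋₁*; the amplitude point at (*tᵢ*, *aᵢ*). Both are resampled
  with a natural cubic spline (`scipy.interpolate.CubicSpline`,
  `bc_type="natural"`) evaluated on a 5 Hz grid; queries outside the knot
  span are clamped to the boundary value.
- **Segmentation** — each annotated minute (half-open windows
  [60k, 60(k+1)), 0-based) becomes one 2×300 segment (5 Hz × 60 s). The
  5 Hz / 300-sample grid is the value that makes the classifier's stem
  produce a length-100 feature map at stride 3. A minute is rejected as
  abnormal iff fewer than 20 peaks fall in the ±5 s-padded window, any RR
  inside the minute leaves [0.3, 2.0] s, or the spline preconditions fail
  (fewer than 4 support points or a zero-variance channel). Segment count
  always equals labelled minutes minus rejections. Each channel is z-scored
  per segment; the pre-normalization mean/std are stored for bookkeeping.

The 20-peak minimum and the [0.3, 2.0] s RR band are this package's
concrete, configurable instantiation of "abnormal segment removal";
likewise the per-segment z-score is our normalization choice. Filtering is
done once, before detection.

## Classifier

A 1-D residual network of four stages whose convolutional layers each run
four parallel same-padded convolutions (kernels 3/5/7/9, equal per-branch
widths 16/32/64/128) concatenated along channels, so stage widths are
64/128/256/512. Stem: kernel-7, 64-filter, stride-3 convolution; then a
3-wide stride-2 max pool. Two residual blocks of two layers per stage;
stride 2 in the first layer of the first block of stages 3–5 (stage 2
keeps stride 1 — the pool already halved the length). Shortcuts are
identities, or 1×1 projections (with normalization) when shape changes.
Each convolution is followed by batch normalization; activation ordering
is the classic conv–BN–ReLU / conv–BN, add, ReLU. Between global average
pooling and the 2-way softmax head sits dropout 0.5. Length arithmetic is
ceil-mode under same-style padding — the only convention that yields the
25→13→7 progression. For a 2×300 input the feature maps are
(64,100) → (64,50) → (64,50) → (128,25) → (256,13) → (512,7).

`count_operations` reports 2 × multiply–accumulates over all branch
convolutions, projection shortcuts and the fully connected layer
(pooling/normalization/activation excluded); the default configuration
gives 143,164,416 FLOPs per forward pass. `multi_scale=False` collapses
each layer to a single kernel-3 convolution with matched output channels —
the plain residual baseline.

The network, its backpropagation and the Adam optimizer are implemented in
NumPy (`msapnea.nnet`): im2col convolutions, batch norm, ceil-mode pooling
with argmax bookkeeping, inverted dropout. Everything is deterministic
given the seed.

## Training

Three imbalance strategies share one loop: plain cross-entropy,
class-weighted cross-entropy CE(p_t) = −α_t log p_t, and the focal loss
FL(p_t) = −α_t (1−p_t)^γ log p_t, which reduces to the weighted CE at
γ = 0. Defaults: γ = 2 (the standard choice from the focal-loss
literature), α_t = inverse class frequency normalized to sum to 1.
Probabilities are clamped at 1e−7 for numerical safety; the gradient is
taken analytically through the softmax.

Optimizer defaults (ours; all exposed in `TrainConfig`): Adam, learning
rate 1e−3, batch 64, 30 epochs. The train/validation split is **by
record** so minutes of one recording never straddle the split (a single
record falls back to a tail split over minutes). After each epoch the
batch-norm running statistics are recalibrated over the training split
with cumulative-average momentum: with the few gradient steps of
desk-scale runs the default exponential estimate lags the true feature
statistics badly enough to distort eval-mode predictions.

## Per-recording diagnosis

AHI = 60 · n_SA_segments / T with T the scored minutes of the recording —
apneic minutes per hour. Categories: A iff AHI > 10, B iff 5 < AHI ≤ 10,
C otherwise; SA verdict iff AHI > 5, so an AHI of exactly 5 is C/not-SA.
AUC uses the rank-based (Mann–Whitney, midrank-tie) estimator. Undefined
ratios (zero denominators) are reported as undefined, never as 0.

## Problem sizes and numerical choices

Training experiments run a reduced configuration (`desk_config`: quarter
branch widths, one block per stage, 16 stem filters) — the same topology
at a size that trains in minutes on one CPU core; the full-width
configuration is used for every shape and operation-count check and runs
forward in milliseconds. Standard experiment sizes: a 200-minute balanced
set (4 records × 50 min) for held-out accuracy, and a 150-minute 1:9
imbalanced set (5 records, 10% apneic minutes) over 5 seeds for the
loss-strategy comparison.

Known limitations: the detector is tuned for upright QRS complexes of
roughly constant polarity; recordings where labels outnumber full minutes
are truncated with a warning; and no attempt is made to separate hypopnea
from apnea or obstructive from central events — per-minute labels are
binary by construction.
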