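# Methods

This note documents the models, the numerical choices, and the limits of
what the test suite establishes. It is the package's own account of its
design; empirical claims below are exactly the quantities the tests and
`scripts/acceptance.py` compute.

## Signal preprocessing

The chain is baseline correction → notch → band-pass, applied to whole
recordings before any epoching so that filter transients never sit at
epoch boundaries.

* **Baseline correction** removes the per-channel mean.
* **Notch** (default 50 Hz, quality 30; 60 Hz by argument) is a
  second-order IIR notch applied forward-backward. Forward-backward
  application doubles the stopband rejection and cancels phase; the
  measured rejection of a 50 Hz tone is ≈ 29 dB while a 10 Hz tone
  passes within 0.01 dB.
* **Band-pass** (default 1–100 Hz) is a Hamming-window FIR applied
  forward-backward (`filtfilt`), hence exactly zero-phase. The tap count
  is `3.3·fs / transition` with the transition width tied to the lower
  edge (`low/2`, floored at 0.05 Hz and capped so the reflect padding
  still fits the record). The upper edge is clipped just below Nyquist so
  1–100 Hz is usable at 250 Hz sampling. A 0.2 Hz drift is attenuated to
  < 1 % RMS; tones pass with zero cross-correlation lag.
* **Band splitting** applies the same band-pass per canonical band.
  Delta is implemented as 1–4 Hz: the front-end already high-passes at
  1 Hz, so a nominal "< 4 Hz" delta band has no content below 1 Hz.
* Independent-component artifact removal is intentionally out of scope;
  `external_clean_hook` accepts a recording cleaned by external tooling.

## Continuous wavelet transform

* **Mother wavelet**: complex Morlet, ω₀ = 6 (the common EEG choice; at
  this bandwidth the admissibility correction term is ~1e-7 and is
  omitted). Scale maps to pseudo-frequency as f = ω₀/(2πa).
* **Normalization**: L2 (a^{-1/2}) by default, L1 (1/a) by option. The
  choice only rescales rows; ridge positions are unaffected for narrow
  relative bandwidths.
* **Discretization**: per scale, FFT convolution of the signal with the
  sampled, conjugated, time-reversed wavelet times dt, kernel truncated
  at ±6 standard deviations of the Gaussian envelope. A literal
  Riemann-sum evaluation of the defining integral (`cwt_reference`) is
  kept as a slow cross-check; the two agree to ~1e-9 relative and find
  the same ridges for 2–40 Hz test tones on a 48-scale grid.
* **Scale grids** are log-spaced in center frequency across each band
  (first scale ↦ band.high, last ↦ band.low).
* **Rendering**: |W| is min–max normalized per image (constant-magnitude
  input maps to all zeros by convention) and resampled bilinearly to the
  target size; resampling at the native size is the identity. Images are
  single-channel; no colormap is baked in. Default size 64×64 —
  sufficient for the 2-way tasks here and affordable on one CPU.

## Base networks

Both are pure functions of a flat name → array parameter dict, so the
meta-learner can adapt copies functionally.

* **CNN-Transformer**: two 3×3 conv+ReLU stages each followed by 2×2 max
  pooling, then batch normalization and dropout (default rate 0.25,
  disabled in the desk-scale profile); the conv grid is average-pooled to
  at most `token_grid`² tokens (default 8×8; how conv features become
  tokens is an open design choice and this is ours), linearly projected
  with a learned positional embedding,
  passed through two standard transformer encoder layers (multi-head
  self-attention → add&norm → feed-forward → add&norm), mean-pooled and
  classified by a linear head. Defaults: widths (16, 32), 4 heads, model
  dim 64, FFN dim 128.
* **Residual network**: a stride-2 stem convolution (with batch norm),
  one 2×2 max pool, then eight residual blocks
  `x + BN(conv(ReLU(BN(conv(x)))))` at constant width with extra max
  pools after blocks 2 and 4, global average pooling and a linear head.
  This stem-plus-eight-block layout is sometimes loosely called
  "ResNet-18"; what is implemented is exactly the eight two-convolution
  blocks. Batch normalization
  inside the residual branch is a deliberate addition: without it the
  8-block stack diverges under inner-loop adaptation at usable learning
  rates (observed, not hypothetical). The skip path is a pure identity,
  so zero convolution weights give an exactly-identity block.
* **Batch normalization** always uses current-batch statistics with no
  running averages — the transductive convention standard in episodic
  meta-learning. A consequence used by the tests: duplicating a whole
  batch leaves every logit unchanged.
* **Initialization**: He-normal for convolutions, Xavier-normal for
  attention/linear maps, zero biases, seeded; float32 by default with a
  float64 option for finite-difference tests.

## Meta-learning

* **Inner loop**: `steps` plain gradient-descent updates of the support
  cross-entropy, θ′ = θ − α∇L; `steps=0` returns the parameters
  untouched. The original parameters are never mutated.
* **Outer loop**: one plain gradient step on the summed post-adaptation
  query loss. No momentum or adaptive optimizer — fidelity to the plain
  update rule; the two mixing logits get their own learning rate
  (`weight_lr`, default 1.0) because two scalars pooled with thousands of
  network weights would otherwise barely move.
* **Gradient order**: `second` (default) retains the inner-update graph
  and differentiates through it — verified against central finite
  differences (quadratic task families, conv classifiers) and against an
  analytic `(I − αH)·g` chain rule for a linear-softmax model. `first`
  detaches the inner gradients, making the outer gradient exactly the
  query gradient at the adapted point.
* **Dual combination**: each base model inner-adapts on its *own* support
  loss (the smallest coupling consistent with per-model adaptation; the
  alternative of adapting on the combined loss would let a broken model
  free-ride on the other's gradients). The outer objective scores
  `softmax(mixing logits) · (logits_A, logits_B)`; the weights are
  normalized by construction and learned end to end.
* **Task sampling**: per task and class, K support + Q query examples
  drawn without replacement (disjoint by construction); class slots are
  assigned in sorted label order. Ties at prediction go to the lowest
  class index.
* **Paper-faithful defaults**: K = 10 shots, 20 tasks per meta-iteration
  batch, α = β = 0.001, 3 adaptation steps. "Number of tasks 20" is
  interpreted as tasks per outer batch (a fixed total of 20 tasks is
  inconsistent with training runs of ~900 iterations). Query size (5 per
  class) and iteration counts are free choices. Meta-testing reuses the
  training adaptation-step count.
* **Desk-scale profile** (used by the acceptance tests and script, sized
  for a single CPU with a numpy backend): widths (8, 8)/8, model dim 16,
  2 heads, token grid 4, no dropout; first-order gradients, 1 task per
  iteration, α = 0.02, β = 0.05, 150–300 iterations. These are capacity
  and budget choices, not claims about the full-scale configuration.

## Synthetic data: the stated world

* **EEG cohort**: each channel is a sum of per-band components (eight
  random-phase sinusoids snapped to the Fourier grid of the record, so a
  periodogram sees no leakage across band edges), each rescaled to its
  exact target RMS, plus additive white (optionally pink) noise. Total
  signal scale 20 µV RMS, default noise 5 µV. The class contrast is a
  band-power shift: pre-deprivation alpha-dominant
  (0.15/0.15/0.35/0.25/0.10 across delta…gamma), post-deprivation
  slow-wave rebound (0.35/0.25/0.20/0.15/0.05) — the physiologically
  expected direction of homeostatic sleep pressure, used here as a
  configurable stand-in, not a claim about any particular cohort.
  Defaults: 13 subjects per class, 250 Hz, F4+C4, 20 s per recording,
  2 s epochs.
* **Scalogram benchmark**: smoothed Gaussian random fields squashed into
  [0, 1] by tanh, with the two classes offset by ±separation/2 along a
  *fixed* smooth spatial pattern of unit RMS. The pattern is a property
  of the world, not of the sampling seed, so datasets drawn with
  different seeds share one class definition; separation = 0 makes the
  classes identically distributed. Separation 3 (the benchmark setting)
  is easy for a trained network yet not trivial for an unadapted one;
  separation 5 is linearly separable by a nearest-centroid rule on raw
  pixels (> 0.9 accuracy, tested).
* **What a green test does not establish**: the synthetic world has
  stationary narrowband signals, no artifacts (blinks, EMG), no
  inter-subject variability beyond resampling, and a spatially fixed
  class signature. Success here validates the machinery — filters,
  transform, meta-gradients, weighting — not clinical performance.

## Evaluation

* Metrics are computed as fractions and reported as percentages in fold
  tables. F1 with no true or predicted positives is defined as 0 (with a
  warning).
* Cross-validation is stratified and, by default, grouped by subject so
  no subject's epochs straddle a fold (image-level splitting is available
  by flag but leaks subject identity).
* The paired t-test uses the k−1-denominator standard deviation and a
  two-sided p from Student's t. Identical fold vectors return t = 0,
  p = 1; zero-variance *nonzero* differences are an error (t undefined).
  For df = 4 the p-value is cross-checked against the closed form
  P(T>t) = 1/2 − (3/4)s + (1/4)s³, s = t/√(t²+4), to 1e-12.
* Feature export returns the weight-scaled concatenation of both models'
  penultimate activations; projection (t-SNE etc.) is delegated to
  external tooling.

## Numerical choices and degenerate inputs

* The autodiff engine expresses every vector-Jacobian product in traced
  primitives, so gradients of gradients are exact by construction;
  convolution is im2col + matmul, making its double-backprop follow from
  the linear primitives. Max reductions split ties evenly; ReLU and
  dropout masks are constants of the backward pass.
* Python scalars stay off the tape and preserve float32 under numpy's
  weak promotion.
* Divergence guard: a meta-loss above 1e6 (or non-finite) aborts training
  with the iteration index.
* EDF output quantizes to 16 bits over the per-channel range and
  truncates to whole seconds; the lossless interchange format is the
  `.npy` + JSON sidecar pair.

## Known limitations

* Second-order training at realistic image sizes is slow on one CPU; the
  first-order option is the practical default at desk scale.
* Only binary tasks are exercised end to end (the task sampler handles
  N-way, but metrics are binary).
* The mixing weights are global (one pair for the whole model), not
  task-conditioned; a task-adaptive inner-loop update of the logits is a
  natural extension that was deliberately not implemented.
* EDF support is minimal (single sampling rate, 16-bit, 1 s records) —
  enough for interchange, not a general EDF library.
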