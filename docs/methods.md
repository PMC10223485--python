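# Methods

This note documents the models, procedures and numerical choices behind
`falldet`, in the spirit of the methods documentation that simulation and
statistics packages ship alongside their APIs.

## Problem setting

The package classifies fixed-width windows ("blocks") of waist-worn IMU
data — tri-axial accelerometer (g) plus tri-axial gyroscope (deg/s) sampled
at 200 Hz — into three event classes: **non-fall** (activities of daily
living), **pre-fall** (the transition from a controlled to a dangerous
state that may end in a fall), and **fall** (the descent, impact and its
aftermath).  Pre-fall detection is the clinically interesting case: it is
what would let a wearable trigger a protective device before impact.  Falls
are fast (the descent itself lasts on the order of 0.8 s) and rare relative
to daily activity, so the pipeline is built around per-event metrics and
class-weighted training rather than pooled accuracy.

## Preprocessing

1. **Filtering.** Each channel is passed through a low-pass Butterworth
   filter, default 4th order with a 5 Hz cutoff, applied forward–backward
   (zero phase).  The order/cutoff defaults are standard for human-movement
   accelerometry; zero-phase application is essential here because every
   timestep carries a label, and a causal filter's group delay would shift
   the signal relative to its annotations.  The closed-form magnitude
   response of the combined pass, `|H(f)|^2` with
   `|H(f)| = (1 + (f/f_c)^{2n})^{-1/2}`, is exposed for testing.
2. **Normalization.** Per-channel statistics are computed on
   training-subject trials only and frozen.  The default mode is z-score
   followed by hard clipping to [-1, +1].  Z-scores are unbounded, so
   "z-score into [-1, +1]" is realised as z-score + clip; min–max scaling
   to [-1, +1] and a tanh-squashed z-score are selectable alternatives.
   A zero-variance channel gets σ := 1 (and is recorded), leaving it
   centered instead of undefined.
3. **Segmentation.** Trials are cut into blocks of 256 samples (1.28 s at
   200 Hz) with 50% overlap: stride = round(W·(1−overlap)), windows
   `[s, s+W)` at stride multiples, trailing partial windows discarded.
   All indices are 0-based and half-open.
4. **Block labeling.** A block's label is the majority class of its 256
   per-timestep labels.  Ties are broken by severity, FALL > PRE_FALL >
   NON_FALL, on the grounds that a missed fall is costlier than a false
   alarm.  The rule is permutation-invariant in the window's labels.

Filtering precedes normalization and segmentation; since the filter is
whole-trial and linear, filtering commutes with segmentation.

## Architecture

The classifier is a **class-based ensemble with a shared head**:

    E(x) = argmax( ε₁(f(x)), ε₂(f(x)), ε₃(f(x)) )

where `f` is a convolutional feature extractor shared by all classes and
`ε_c` is an independent recurrent sub-model emitting a one-vs-rest sigmoid
score for class `c`.  One sub-model per target class lets each branch
specialise; the shared head keeps the parameter count small.

* **Head.** `head_blocks` (default 3) *skipped convolution blocks*: two
  1-D convolutions (depthwise-separable by default, standard selectable,
  kernel 5) with an additive shortcut — a 1×1 projection when the channel
  count changes — followed by max (or average) pooling with stride 2.
  Activation is swish by default (ReLU selectable).  A (256, 6) block
  becomes a (32, 16) feature map with the default three width-16 blocks.
  The block internals (two convolutions per block, kernel 5, projection
  shortcut, pool stride 2) are this package's concrete realisation of a
  residual convolution unit; all are configurable.
* **Sub-models.** Each class's branch reads the feature map as a 32-step
  sequence: `recurrent_layers` (default 2) stacked recurrent cells of
  width 16 (LSTM default; GRU and bidirectional LSTM selectable), dropout
  (default 0.5) after the recurrent stack, then a single sigmoid unit.
  Scores are one-vs-rest probabilities and do not sum to one across
  classes.
* **Fusion.** Argmax over the per-class scores, with the same severity
  tie-break as block labeling.  Reference combiners are provided for
  comparison experiments: a weighted-average fusion `argmax(ω_c·ε_c(x))`
  (weights default to 1; no principled default exists, so they are purely
  configuration) and a stacked ensemble whose sub-model outputs feed a
  final dense softmax learner.

The layer engine (convolutions, pooling, recurrent cells, dropout, dense,
Adam) is implemented in numpy with hand-derived backward passes inside the
package, and is verified in the test suite against central finite
differences and closed-form parameter counts — LSTM `4(u(u+i)+u)`, classic
GRU `3(u(u+i)+u)` — so the GRU is always the strictly smaller cell.

## Training protocol

* **Subject-wise split.** A held-out subject set (for the full 38-subject
  cohort the convention is four young + two elderly, drawn
  deterministically from the declared groups by `split_seed`; explicit ID
  lists are accepted) forms the test set.  Remaining blocks are split
  80/20 into train/validation, stratified per block label (per-trial
  splitting is available as an option).  Subject disjointness between test
  and train∪val is asserted on every run.  Normalization statistics are
  fit after the test subjects are fixed, on training-side subjects only.
* **Loss.** Sum over classes of class-weighted binary cross-entropy
  between each sub-model's score and the one-hot target (each branch is a
  one-vs-rest binary task).  Weights default to inverse frequency
  `N/(n_classes·N_c)`, normalized so the smallest weight is 1; explicit
  weights may be supplied.  The training path computes the loss from
  logits via softplus for stability; the score-level form clips
  probabilities at 1e-7.
* **Optimisation.** Adam, learning rate 0.0005, batch size 128, up to 200
  epochs (the desk-scale experiments below use 30).  Every training batch
  passes through the online augmentation step.  The returned weights are
  those of the epoch with the lowest validation loss; early stopping is
  optional (off by default).  A non-finite loss aborts with a diagnostic.
* **Replicates.** Experiments are run as three seeded replicates and
  reported as mean ± sd.  All randomness — initialisation, shuffling,
  augmentation, dropout — derives from explicit seeds; identical seeds
  reproduce losses bitwise.

## Online augmentation

Half of each training batch (`floor(0.5·B)` blocks, drawn uniformly
without replacement) is replaced in place by a transformed copy; each
selected block receives exactly one transform, drawn from the configured
probabilities (default uniform over the three).  Nothing is written to
disk.  The transforms are label-preserving:

* **Rotation** — one random 3-D rotation per block (axis uniform on the
  sphere, angle uniform in (−π, π), Rodrigues form), applied to every
  timestep and every xyz triplet.  Accelerometer and gyroscope triplets
  share the matrix because a physical re-orientation of the device rotates
  both sensors identically — that is the effect the transform simulates.
* **Scaling** — one scalar per block from N(1, 0.1) (a per-channel variant
  is available but off by default; the per-block scalar is the literal
  reading of "multiplying a window by a random scalar").
* **Jitter** — element-wise Gaussian noise, σ = 0.01.

## Evaluation

Per-event one-vs-rest counts (TP, FP, TN, FN) come from the 3×3 confusion
matrix; accuracy, sensitivity and specificity follow the formulas above.
A 0/0 ratio is reported as missing (NaN) rather than 0 or 1, so degenerate
test sets cannot silently inflate results.  One-vs-rest ROC curves are
swept over each class's score column (all unique thresholds, endpoints
included); AUC is trapezoidal and equals the pairwise-ordering probability,
which the tests verify by enumeration.  The report never prints a pooled
accuracy — with NON_FALL dominating the block population it would be
misleading — only the per-event table, the confusion matrix, and per-class
ROC points.

## Synthetic data generator

The generator emulates the structure the pipeline assumes, so everything is
testable without real recordings.  Signals are phenomenological: gravity
projection + per-subject gait oscillation (young 1.7–2.2 Hz, elderly
1.3–1.7 Hz, ±20% amplitude scaling) + event templates + Gaussian noise;
a second accelerometer channel triple is emitted with a different noise
floor so the 9-channel file layout is faithful.  Trial kinds follow the
three annotation patterns: plain daily activity; a near-fall whose hazard
phase (rising tilt, 6–9 Hz wobble, gyro surge) resolves back to normal
activity; and a fall with a 0.3 s pre-impact hazard, a 0.8 s descent
containing a free-fall dip and an impact peak of ~3 g (easy preset), and a
post-impact lying-still period.  The lying-still period keeps the FALL
label: a person immobile on the ground is not performing a daily activity,
and without a multi-second fall-state span a 256-sample majority vote could
essentially never produce FALL blocks.  For the same reason the near-fall
hazard lasts ~3 s (a stumble plus recovery) whereas the pre-impact hazard
of a completed fall is only 0.3 s.

The easy preset (4 young + 2 elderly subjects, 36 trials each, cycling the
three kinds) yields ≈3,600 blocks at roughly 8:1:1 class imbalance —
360 pre-fall and 360 fall blocks — with ADC-count emission in the SisFall
on-disk dialect so tests exercise the real reader.  The hard preset
overlaps the amplitude distributions (0.5 g gait, 1.2 g impacts, 4× noise)
to exercise imbalance handling rather than guarantee success.

**What passing tests show — and don't.**  Success on the easy preset shows
the pipeline is wired correctly end to end: leakage-free subject-wise
protocol, learnable representations, functioning augmentation and
optimisation.  It does not certify performance on real falls: the generator
does not model sensor saturation or drift, inter-device variation, the
diversity of real ADLs (sitting, stairs, vehicle rides), or genuinely
ambiguous near-falls, and its class signatures are cleaner than reality.
Results on real recordings require the real dataset and its per-sample
annotations.

## Desk-scale experiment sizes

The bundled end-to-end experiment trains the default architecture on the
easy preset (6 subjects; one young + one elderly held out, so test metrics
are computed on ~1,200 blocks from unseen subjects) for up to 30 epochs per
replicate over three seeds.  These sizes keep a full run in the
single-digit minutes on one CPU core while leaving each minority class with
hundreds of test blocks.

## Known limitations

* The numpy engine is CPU-only and unbatched across replicates; it is
  sized for desk-scale experiments, not for training on full real cohorts.
* The stacked-ensemble reference combiner is provided for architecture
  comparisons; its training path is exercised far less than the class-based
  ensemble's.
* The weighted-average fusion weights have no data-driven default.
* The CLI `preprocess` step fits normalization statistics on all subjects
  not listed in `split.test_subjects`; if test subjects are instead drawn
  by seed at training time, list them explicitly in the config to keep the
  normalization leakage-free (the library's `run_experiment` handles this
  ordering automatically).
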