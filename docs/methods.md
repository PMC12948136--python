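# Methods

## 1. Synthetic cohort with planted evidence

Each trial of the generator mimics one over-ground walking recording:

- **Markers** (585 × 156 at full size, 100 Hz): channel *c* belongs to
  marker *c div 3* and coordinate *c mod 3*. Every channel is
  `offset + A·sin(2πft + φ) + subject effects + Gaussian noise`, with
  stride frequency `f = c0 + c1·v` (defaults 0.5 + 0.5·v Hz) driven by
  the walking speed `v` drawn uniformly from the class range. Channels
  in the class's planted group receive a ×2 amplitude multiplier.
- **GRF** (585 × 24): per-stance double-hump vertical force (two
  Gaussians) with peak ∝ (1 + 0.2·v), sourced at 1500 Hz but stored on
  the 585-frame marker grid.
- **EMG** (8985 × 8, 1500 Hz): rectified Gaussian-envelope bursts
  phase-locked to the gait cycle with duty cycle decreasing in `v`.
- **F&M** (8985 × 12): lever-arm-scaled transforms of the GRF.

Trial duration shrinks with speed (`n_cycles / f`, ±10% jitter); all
tensors are zero-padded to fixed lengths and the unpadded length per
modality is recorded. Subject random effects (amplitude, offset,
cadence) are shared across a subject's trials so subject-wise splits are
meaningful.

Two deliberate design choices keep the planted channels the *only*
channel-selective class evidence in the marker block: the global marker
amplitude is speed-independent by default (`speed_amplitude_gain = 0`),
and all channels share the fundamental stride frequency. Class identity
is therefore carried by (a) the planted amplitude groups, (b) stride
frequency, and (c) trial duration — so a faithful explainer must
concentrate relevance on the planted channels rather than on arbitrary
frequency-coded ones.

`scaled_modality_specs(factor)` divides the temporal lengths (and
nominal rates) by an integer factor; the channel layout is untouched.
The test suite and the acceptance script run at factor 10
(58/898-frame trials), which preserves every protocol property while
keeping a full cross-validation under two minutes on one CPU.

## 2. Models and cross-validation

Deep families are built from a numpy autodiff stack: per-modality
1-D CNN encoders (conv–ReLU–pool, global average pooling, dense
embedding) whose embeddings are concatenated into a shared dense
softmax head. `quads_cnn` uses four independent encoders (markers, GRF,
EMG, F&M); `fusion_cnn` shares the embedding projection across streams;
`cnn_lstm`, `tcn`, `gru` and `transformer` swap the encoder family.
Baselines (`lda`, `qda`, `svm`) operate on flattened standardized
tensors via scikit-learn.

Three experiment designs share one `SplitPlan` abstraction:

1. **Experiment 1** — stratified sample-wise 10-fold CV;
2. **Experiment 2** — subject-wise 5-fold CV with 5 held-out subjects;
3. **Experiment 3** — subject-wise with 10 held-out subjects.

Leakage rules: channel statistics (mean/scale over unpadded frames
only) are fitted on each fold's training partition and applied to its
validation and test partitions; subjects never straddle a subject-wise
boundary. A stratified validation slice (10%, at least one sample per
class) is carved from each training portion for early stopping. All
models are evaluated under the *same* plan, so per-fold metric
differences are genuinely paired and compared with a paired t-test.

## 3. Layer-wise relevance propagation

`forward_trace` records every layer's input/output; `lrp_backward`
redistributes the chosen logit (never a softmax probability) backwards.
Linear and convolutional layers use the generalized "gradient trick":
with stabilized pre-activations `z`, the input relevance is
`x ⊙ ∂(z · (R/z))/∂x`, which implements

- **z-rule** — exact conservation on bias-free ReLU networks (verified
  to ~1e-15 relative error);
- **epsilon-rule** — sign-consistent stabilizer `z + ε·sign(z)`;
- **alpha-beta** — separate positive/negative contribution passes with
  `α − β = 1` (e.g. α1β0 keeps only excitatory evidence);
- **flat** — uniform redistribution over the receptive field;
- **preset composite** — epsilon in dense layers, α1β0 in convolutions,
  flat in each stream's first layer.

Pooling layers route relevance through the max/average path; batch
normalization in eval mode is folded as a diagonal affine map. LSTM
heads are handled with an additive cell decomposition (relevance flows
through the cell state, split between the forget-gated previous cell
and the input-gated candidate); GRU and attention heads raise
`UnsupportedArchitectureError` rather than return silently wrong maps.
Gradient, gradient×input, guided backprop and deconvnet baselines share
the same analyzer interface.

## 4. Class-level aggregation protocol

Per class: take the relevance maps of *correctly classified* samples of
that class, normalize each by its max absolute value, average
elementwise, smooth along time with the (1/4, 1/2, 1/4) kernel (three
passes by default; the boundary kernel is renormalized so every pass
preserves total mass exactly), min–max rescale to [0, 1], select the
top-200 cells (ties broken by flat index for determinism), and fold
channel scores onto markers by summing each marker's three coordinates.

**Fold-wise explanation.** Each sample is explained by the
cross-validation fold model that held it out, and the class profile
aggregates those held-out maps across folds. Single-model profiles are
noticeably less stable: an individual network may encode a class partly
by the *absence* of an adjacent class's planted evidence, which
fold-averaging washes out. With the fold-wise protocol the planted
channel groups are recovered at ≥ 88–100% per class (top-k with k =
twice the group size).

## 5. Perturbation audit (MoRF / AOPC)

The time×channel map is tiled 7×7; tiles are sorted by summed absolute
relevance (most relevant first, ties by row-major index) and replaced
step by step with uniform noise drawn from each channel's observed
range, keeping the other modalities fixed. The perturbation curve
records the target-class probability after 0..L steps and

`AOPC = mean_{k=0..L} (f(x⁰) − f(xᵏ))`.

A linearly dropping curve with step `d` gives the closed form
`AOPC = d·L/2`, used as an oracle. Analyzer quality is the paired
t-test of per-sample AOPC under the analyzer's ordering versus a random
tile ordering over ≥ 20 correctly classified samples.

## 6. Statistics

Macro-F1, MCC and one-vs-rest AUC come from scikit-learn behind
`evaluation.py`; the paired t-test (`t = mean(d)·√n / sd(d)`, df = n−1)
is validated against the hand example d = (1, 2, 3) → t = 2√3 and
calibrated under a simulated null (empirical type-I error ≈ 0.05 over
500 repetitions).
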