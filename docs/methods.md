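# Methods

## Problem and model

The package detects the onset of slow (delta-range) EEG activity following a
generalized tonic–clonic seizure. The input is a ten-second window of
ten-channel bipolar-montage EEG sampled at 200 Hz — a `(2000, 10)` array —
and the output is a single probability that the window contains the onset.

The detector is a pre-activation residual 1-D convolutional network:

* **Stem**: a 17-tap convolution lifting the 10 input channels to the base
  width `D = 32` (bias included).
* **Six residual blocks** (BN → ReLU → conv → BN → ReLU → conv, two
  convolutions each, twelve in total) across three width stages
  `D, 2D, 4D` = 32/64/128, with kernel size 5 in the first stage and 3
  afterwards. Shortcuts crossing a width change are projected by a biased
  1×1 convolution applied to the pre-activated input; all block
  convolutions carry biases, matching the deep-learning-framework default
  the reference parameter count implies.
* **Anti-aliased temporal downsampling** in blocks 2, 4 and 6: a fixed
  3-tap Gaussian low-pass (σ ≈ 0.79577, taps ≈ [0.238, 0.524, 0.238],
  reflect padding) followed by keeping every second sample, applied to both
  the main path and the shortcut. Temporal lengths run
  2000 → 1000 → 500 → 250. The same σ is used at every stage so the learned
  representation concentrates on progressively lower frequencies.
* **Head**: final BN + ReLU, global max pooling over time (position
  independence: the largest activation of each of the 128 channels is kept
  wherever it occurred), and a bias-free dense unit with sigmoid output.

This reference configuration has exactly **165,664 trainable parameters**
(convolution kernels and biases, BN scale/shift, dense weights), verified
against an independent arithmetic tally in the test suite. The bias-free
output unit is forced by a parity argument: every other parameter vector in
the architecture has even length, so a biased single-unit head could not
produce an even total.

A note on batch normalization placement: one BN precedes each of the twelve
block convolutions and one final BN precedes pooling — thirteen in total,
the standard pre-activation arrangement. The equivalent "each convolution
followed by BN" description gives the identical parameter tally.

### Ablation variants

`build_variant` exposes the technique switches: `no_zscore` (each sequence
normalized by its own scalar mean/sd), `no_l2` (λ = 0), `no_antialias`
(stride-2 convolution on the main path, max-pooled shortcut — same
parameter count), `bs32`/`bs64` (batch size only), `no_discount` (α ≡ 1),
and `baseline` (all four techniques off, batch size 64).

## Training

* **Windowing**: per patient, every ten-second window whose end lies on the
  stride-5 grid anchored at the onset and which satisfies
  `t_f ≥ t_onset` and `t_i ≤ t_onset` is a positive example (the grid rule
  is pinned against a brute-force enumeration oracle). Negatives are drawn
  uniformly **with replacement** from all windows ending strictly before
  the onset, capped at the positive count. Windows crossing a recording
  edge are dropped, never padded.
* **Augmentation**: before training, a seeded 50% of windows are replaced
  by crop-resampled versions — the first `round(u·L)` samples
  (`u ~ U[0.9, 1.1]`) linearly interpolated back to length `L`, scaling
  apparent frequencies by `u`. For `u > 1` the crop extends into the source
  recording when available, otherwise the window's tail is reflected (both
  paths logged). Labels travel with the window: the label track is
  resampled nearest-neighbor and `p` recomputed.
* **Normalization**: each training mini-batch is z-scored with a *single*
  scalar mean and standard deviation over all batch, time and channel
  entries, so successive batches present different overall scales and
  offsets; validation windows are z-scored once with the training
  population's scalar statistics. ε = 1e-8 guards degenerate batches
  (centered only, warning logged).
* **Loss**: discounted binary cross-entropy plus an L2 penalty
  (λ = 0.01) on all convolution kernels:
  α(p) = 0.95 at p = 0, 10p for 0 < p ≤ 0.1, and 1 above — discounting
  windows that overlap less than the first second after onset, and slightly
  discounting all negatives to keep the balanced classes unbiased.
  Predictions are clipped to [1e-7, 1 − 1e-7] inside the cross-entropy.
* **Optimizer**: classical momentum SGD (`v ← βv − η∇; w ← w + v`,
  β = 0.9, no Nesterov), initial rate 1e-4 halved every 15 epochs, batch
  size 16, 75 epochs at full scale. The last incomplete batch of each epoch
  is dropped (batch-wise statistics degrade for tiny batches). All
  randomness — initialization, shuffling, augmentation draws — derives from
  the run seed; two runs with the same seed produce bit-identical
  histories.

The network, backpropagation and optimizer are implemented directly on
NumPy arrays with hand-written per-layer backward passes; every layer's
gradient is verified against central finite differences, and the
convolution forward against an independent `scipy.signal` computation.
float64 is the default; `model.astype(np.float32)` roughly halves training
time and is used for the training experiments.

## Evaluation

ROC-AUC is computed by the rank (Mann–Whitney) statistic — the probability
that a random positive outscores a random negative, ties counted ½ — which
handles ties exactly, unlike trapezoidal curve integration. Thresholded
metrics use the strict rule: a score of exactly 0.5 is negative.

## Salience

For an input window `x` (normalized exactly as at inference) the salience
of timestep `t` is `Σ_f |∂y/∂x[t, f]|` over the ten channels, computed by
the same backward machinery that trains the network, and normalized by its
maximum for display. The gradient is taken with respect to the normalized
input — the only well-defined choice when z-scoring happens outside the
model. Because of the global-max-pooling head, gradients concentrate on the
timesteps that produced the pooled maxima, so traces are sparse. Degenerate
all-zero traces are flagged, never rescaled.

## Synthetic cohorts

The clinical recordings are protected health information, so all
experiments run on seeded synthetic surrogates that encode exactly the cues
the detector is built to exploit:

* pre-onset: per-channel mixtures of 10 Hz (amplitude 1.0) and 22 Hz (0.6)
  sinusoids with random phases plus white noise (sd 0.5);
* post-onset: a 1.5 Hz slow oscillation of amplitude 3.0, shared across
  channels with weight 0.9 (plus 0.1 independent per-channel phase),
  residual fast activity attenuated to 30%, and the same noise floor;
* per-patient log-normal channel gains (sd 0.3 log-scale) and normal
  channel biases (sd 5 µV) — the scale/offset diversity that batch-wise
  z-scoring is meant to absorb;
* durations uniform on 60–180 s with the onset at a uniform 0.4–0.8
  fraction of the duration; labels are 0 before the onset and 1 after.

A "hard-mode" generator caps the shared-component weight at 0.3, flips the
slow component's sign on a random subset of channels and compresses its
amplitude, emulating the low-correlation onsets that drive false negatives.
Patient-level seeds come from a splittable counter-based scheme, so growing
a cohort never reshuffles earlier patients. All magnitudes are package
choices recorded in the generation manifest; they are not estimates of any
clinical data. The surrogates have no 1/f background, no artifacts and no
non-stationarity beyond the single onset, so success here demonstrates the
pipeline's mechanics and the relative value of its techniques — not
clinical performance.

## Problem sizes used in the automated checks

The distributed test suite exercises the full pipeline at reduced sizes
chosen to keep the whole suite within a desktop-scale run:

* **End-to-end comparison**: 10 training / 4 validation synthetic patients
  (cohort seed 42), 12 positives per patient plus equal negatives
  (240 windows), 120 validation windows at the study prevalence
  (3219/12345), the reference layout at base width 8, float32.
  The full method is checked to reach mean best validation ROC-AUC ≥ 0.85
  over seeds {0, 1, 2} at 20 epochs, and to beat the baseline variant's
  mean best ROC-AUC over ten shared seeds at 8 epochs. Twenty epochs are
  used because the reduced cohort yields ~15 optimizer steps per epoch, so
  the published learning-rate schedule needs more epochs to converge than
  it would with a full-size window set.
* The determinism, loss-decrease and sparsity checks use 2-patient
  cohorts with short recordings and base width 4.

## Known limitations

* The exact block layout and kernel sizes of the original network are not
  published; the reference configuration here is the package's own
  reconstruction, constrained to the stated depth, widths, downsampling
  structure and exact parameter count.
* Training at the full published scale (134 patients, 75 epochs) is
  supported by the API but is slow in pure NumPy; the shipped experiments
  run scaled down.
* The published clinical metrics cannot be reproduced without the
  protected data; nothing in this package estimates them.
* EDF output quantizes to 16 bits; the columnar dialect is the lossless
  interchange format.
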