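# Methods

`octseg` segments the epidermis in dermatological optical-coherence-
tomography (OCT) B-scans with a compact encoder-decoder U-Net, and
quantifies the clinically relevant readout — epidermal thickness (ET) —
from the resulting binary masks. Because clinical OCT datasets of actinic
keratosis are not publicly available, the package ships a synthetic
phantom generator that emulates the structure of such B-scans; every
pipeline stage is developed and validated against phantoms whose ground
truth is known exactly.

## Segmentation model

The network is a symmetric U-Net:

* an encoder of `encoder_depth` blocks (default 2), each two 3×3
  convolutions + ReLU followed by 2×2 max pooling;
* a bottleneck block of the same two-convolution form;
* a decoder mirroring the encoder, where each level upsamples with a
  **2×2 learned transposed convolution (stride 2)** — small upsampling
  filters keep the parameter count and CPU cost down — concatenates the
  matching encoder output through a skip connection, and applies two 3×3
  convolutions + ReLU;
* a final 1×1 convolution producing one logit per pixel, squashed by a
  sigmoid into an epidermis probability.

All convolutions use zero ("same") padding, so the probability map has
exactly the input's spatial size; input dimensions must be divisible by
`2**encoder_depth`, and indivisible sizes are rejected with guidance
rather than silently padded, because silent padding would break the
shape-preservation contract. Channel widths start at `base_filters`
(default 16) and double per level (16, 32, bottleneck 64; 116,753
parameters at the default). Weights are He-initialized from an explicit
seed. Hidden activations are ReLU and the output is a sigmoid — the
conventional choices for this architecture; batch normalization is not
used.

The layers, backpropagation, and the Adam optimizer are implemented
directly on numpy arrays (`octseg.nn`): 3×3 "same" convolutions are
evaluated as nine shifted BLAS matmuls, which avoids the memory-bound
im2col copy and keeps single-core training of the default model at
roughly half a second per 256×256 image (forward + backward). The
analytic gradients are verified against central-difference numerical
differentiation in the test suite (median relative error below 1e-7 in
float64; coordinates sitting exactly on ReLU kinks are excluded from the
worst-case assertion because the numerical quotient itself is invalid
there).

## Training strategy

Datasets are split once into 20% held-out test images and 80%
training images, of which a `validation_fraction` (default 0.2) forms the
internal validation subset — a 60-image dataset yields the 48/12
convention with 38 train / 10 validation inside the 48. Test items are
never touched during training or validation; the split, shuffling, and
weight initialization are all keyed to explicit seeds.

Images are resized with anti-aliased bilinear interpolation and scaled
to [0, 1]; masks are resized nearest-neighbour so they remain strictly
binary. Training minimizes pixel-wise binary cross-entropy with Adam
(learning rate 0.001), logging per-epoch train/validation loss and pixel
accuracy. Validation loss drives two callbacks: reduce-on-plateau
(factor 0.5 after 5 stagnant epochs) and early stopping (patience 10),
after which the best-validation-loss weights are restored. The loss
function, validation fraction and callback patiences are this package's
defaults — all configurable and echoed into every run record.

**Overfit rule.** A run is flagged as overfit when the final validation
loss exceeds the final training loss by more than `gap_margin` (default
0.1) *and* the least-squares slope of validation loss over the last
`trend_window` epochs (default 5) is positive while the training-loss
slope is non-positive — i.e. the curves are genuinely diverging, not
merely offset.

## Evaluation metrics

For a predicted mask vs. ground truth, the suite reports accuracy,
precision, recall, Jaccard (IoU), Dice, mean absolute error (MAE), and
the Hausdorff distance, with qualitative bands: overlap scores > 0.7
acceptable, > 0.8 good, > 0.93 excellent; MAE < 1 px good, 1–1.5 px
acceptable; Hausdorff < 25 px good, 25–70 px acceptable.

Numerical conventions:

* MAE is the per-pixel mean |y − ŷ|, which on binary masks equals
  (FP+FN)/N and is therefore dimensionless despite often being quoted in
  "pixels"; a probability-map mode exists behind a flag.
* Boundaries are foreground pixels 4-adjacent to background or to the
  image border; coordinates are 0-based (row, col) with row increasing
  with depth.
* Hausdorff uses the exact max-form (no percentile variant) with
  Euclidean distances, computed with a k-d tree but asserted in tests to
  match the O(|A|·|B|) brute force exactly. An empty boundary raises an
  error that distinguishes empty prediction (segmentation failure) from
  empty truth.
* Precision (or recall) with a zero denominator is reported as NaN with
  a warning and scored 0 in aggregates; Dice/Jaccard of two empty masks
  is 1, since agreement on emptiness is genuine agreement.

The identities Dice = 2J/(1+J) and accuracy = 1 − MAE (binary inputs)
hold exactly on every confusion table and are asserted as invariants.

## Epidermal thickness and agreement

Per column, ET = (last foreground row − first foreground row + 1); a
column fragmented by a noisy prediction is measured across its outer
envelope (a strict mode flags such columns instead). Columns without
foreground are excluded from the mean — the documented choice, rather
than zero-filling. The pixel mean is converted to µm by an explicit
axial pitch (default 5.5 µm/px, a typical swept-source axial
resolution); every µm output carries the factor used, since results
scale linearly with it.

Agreement between two ET series uses Pearson correlation and
Bland–Altman statistics: bias = mean(auto − manual), 95% limits of
agreement = bias ± 1.96·SD with the n−1 sample SD. The paired t-test
across B-scan positions (25%/75% peripheral vs 50% central) is two-sided
with significance at p < 0.05; all-zero differences report p = 1 and
constant non-zero differences are marked degenerate instead of
producing an infinite t statistic.

## Phantom generator

Each phantom stacks, top to bottom: near-zero air (reflectivity 0.03), a
bright 2-px entrance-surface line (0.95), an epidermis band (0.45)
terminated by a smooth dermal-epidermal junction, and a dermis (0.75)
attenuating exponentially with depth (default 0.004/px). Surface height
and band thickness vary laterally as sums of four low-frequency
sinusoids with seed-drawn phases, normalized so the profile stays within
mean ± amplitude. With probability `hyperkeratosis_probability` a
raised-cosine region of extra thickness and brighter surface is added;
a Poisson number of hair shadows each darken (×0.1–0.3) a 3–10-column
span below the surface — darkening rather than zeroing, so no mask
column becomes empty. Speckle is multiplicative unit-mean gamma noise
with shape 1/contrast² (first-order OCT speckle statistics: expected
layer intensities are unchanged, contrast controls the relative
standard deviation). `speckle_contrast` spans [0, 1] with 0 meaning
noise-free — the limit used by several tests.

The default canvas is 464×1356 px (a 6-mm lateral field at 4.4 µm
fast-axis sampling, 5.5 µm axial pitch); `quick_spec()` provides a
256×256 preset with the same morphology (surface depth 40 ± 6 px, band
25 ± 8 px, moderate speckle contrast 0.3, hyperkeratosis probability
0.3 with up to 14 px extra thickness, 1.5 expected shadows).

What the phantoms do **not** model: confocal gating, refraction, the
system PSF, sub-resolution layering, real AK lesion morphology
(particularly grade-3 hyperkeratosis), or annotation noise — real
ground truth comes from a human expert whose masks are themselves
variable, while phantom truth is exact. Passing the synthetic end-to-end
test therefore shows the pipeline is correct and trainable, not that it
reaches any particular accuracy on clinical scans.

## Hyperparameter sweep

The sweep enumerates image size × batch size × epochs (default full
4×4×3 = 48-cell grid over {256², 512², 1024², 464×1356} × {2,4,8,16} ×
{50,100,150}; an explicit configuration list can replace the grid). All
configurations share one split; each trains from the same seed,
evaluates on the identical test partition, and records the seven-metric
means, final losses, the overfit flag, wall time (informational only)
and a status — failures are recorded and the sweep continues. Selection
defaults to highest Dice, ties broken by higher Jaccard, then lower
Hausdorff, then fewer parameters; minimum-validation-loss and
minimum-MAE criteria are available.

## Problem sizes used by the test suite and acceptance script

End-to-end runs train on 60 phantoms generated directly at the 256×256
quick preset (48 train+validation, 12 test), batch 2, up to 50 epochs
with the callbacks above, using 8 base filters — the desk-scale
configuration this package uses for its own regression runs; it reaches
the same qualitative regime as the default width at a quarter of the
compute. Unit tests use 64×64 and 32×32 phantoms and 2–8 filters.

## Known limitations

* CPU-only, single-image inference; no data augmentation (mirroring the
  deliberately simple training recipe), no 3-D volumes.
* The numpy training loop is exactly reproducible on one platform, but
  bit-level reproducibility across BLAS builds is not guaranteed.
* ET in µm depends entirely on the supplied axial pitch; the package
  never infers it from device metadata.
* Phantom realism limits are listed above; in particular hair-shadow
  and hyperkeratosis parameters are plausible rather than fitted to
  measured lesion statistics.
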