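# Methods

## The model

`cnmp` implements a medical-image classifier that fuses two feature families:

1. **High-level features (HF)** from a small "coding network" — a CNN with
   six valid convolutions (kernels 11, 11, 9, 8, 9, 8; stride 1, no padding),
   two overlapping 5×5/2 max-pools, optional batch normalization, and ReLU
   after every convolution.  On a 140×140×3 input the final convolution
   collapses to a 1×1×256 tensor; that post-ReLU vector is HF.  A flatten +
   fully-connected layer ("rasterize") maps HF to class scores and a softmax
   turns scores into probabilities.  The network is trained end to end by
   mini-batch SGD with momentum 0.9 on softmax cross-entropy, with the
   learning rate multiplied by a decay factor after every epoch.

2. **Traditional features (LF)** — 17 handcrafted values per image:
   8 texture statistics (mean and standard deviation over the four GLCM
   angles 0°/45°/90°/135° at distance 1 of ASM, entropy, contrast and
   correlation) plus 9 color moments (per-channel mean, standard deviation
   and signed cube root of the third central moment).

Two fusion heads combine the standardized blocks:

* **R fusion** — `NF = (λ·LF, (1−λ)·HF)` followed by a softmax classifier,
  with λ chosen on a grid {0, 0.1, …, 1} by validation accuracy (ties to the
  smaller λ).  Because LF (17) and HF (256) have different lengths, the
  weighting is applied to the concatenated blocks; an elementwise sum is not
  defined between them.
* **MLP fusion** (the CNMP head) — `RF = relu(W·[LF;HF] + b)` with a
  configurable hidden width (default 64), then a fully connected layer and
  softmax, trained by cross-entropy with the same epoch/decay conventions as
  the coding network.  The hidden layer learns the proportions between the
  feature groups and can exploit interactions no fixed λ can express.

## Data pipeline

Images are split 7:1:2 into train/validation/test, **stratified by class**
(both emulated benchmarks are imbalanced, and per-class metrics require
every class in every split).  The per-channel scalar mean RGB of the
*training* images is subtracted everywhere (a per-pixel mean would not be
defined across variable-resolution images).  Each source image contributes
`m` randomly cropped patches: a fixed 420×420 window for fixed-resolution
(histology-like) data or a ⌊2h/3⌋×⌊2w/3⌋ window for variable-resolution
(dermoscopy-like) data, bilinearly resized to 140×140; horizontal/vertical
flips are applied to each patch with probability ½.  Flips act on patches
(not source images) so the patch count is exactly `m·n` for any `m`.  At
test time the softmax outputs of all patches from one source image are
averaged; LF and HF are likewise computed per patch and averaged per source
image.  Splits and cross-validation folds are always drawn over source
images, never patches, so no source image leaks across a split boundary.

## Conventions pinned where the literature varies

* GLCM: symmetric accumulation (each ordered pair counted in both
  directions), normalized to a probability matrix *before* any statistic
  (entropy requires probabilities); gray levels indexed 0..s−1; natural-log
  entropy; `s` defaults to 16 levels (uniform quantization of [0,255] after
  the 0.299/0.587/0.114 luminance conversion) — small enough that 140×140
  patches populate the matrix densely.
* Correlation of a degenerate GLCM (zero marginal deviation, e.g. a constant
  patch) is reported as 0 with a flag rather than NaN, so constant crops
  cannot poison downstream feature vectors.
* Color moment V is the population standard deviation (not the variance);
  S is the signed cube root `sign(μ₃)|μ₃|^{1/3}`, which stays real for
  negatively skewed channels and lives on the intensity scale.
* Pool output arithmetic is `floor((in − window)/stride) + 1` (58 from 120
  with a 5×5/2 pool); convolutions are `in − kernel + 1`.
* Batch normalization sits between each convolution and its ReLU.
* Prediction ties break toward the smaller class label.
* Undefined precision/recall (a class never predicted / never present) is
  reported as NaN, never silently as 0.
* Both feature blocks are z-standardized on training data (zero-spread
  features get scale 1) before any fusion; raw GLCM/moment magnitudes and
  ReLU activations differ by orders of magnitude, and λ would otherwise be
  meaningless.

## Numerical implementation of the network

No autodiff framework is used: layers carry hand-written backward passes in
NumPy.  Convolutions (forward, input gradient, weight gradient) are computed
as correlations via 2-D real FFTs with a channel contraction in the
frequency domain — for this architecture's large kernels (8–11 px) that is
substantially faster on CPU than im2col, and it was verified against both a
direct sliding-window implementation and central finite differences.
Weights are float32, He-initialized (std `sqrt(2/fan_in)`), and every source
of randomness (init, batch shuffling, crop/flip draws, dropout) flows from
explicit seeds, so a fixed seed reproduces identical weights and metrics on
one device (bit-equality across BLAS/FFT builds is not promised).  Dropout
(inverted, on the penultimate feature) is available but off by default.

## Synthetic data: what it emulates, and what it does not

`cnmp.datasets` renders seeded RGB images whose classes differ in oriented
periodic texture (sinusoidal gratings, checkerboards, low-pass blob noise)
and in per-channel color distribution (mean, spread, and skew direction via
a centered half-normal), plus i.i.d. Gaussian pixel noise, clipped to
[0, 255].  Ready-made specs mirror the two emulated benchmarks' bookkeeping:
a histology-like fixture (4 classes, counts 1026/484/804/514, fixed 720×480)
and a dermoscopy-like fixture (374/1626, per-image resolution drawn from a
small set), exercising both crop policies.

The **complementarity fixture** is built so the two feature families carry
disjoint information: texture kind (grating vs checkerboard, amplitudes
matched so the pixel variance is equal) separates classes {1,2} from {3,4},
and luminance-matched color means (equal 0.299R+0.587G+0.114B) separate odd
from even labels.  Consequently texture features alone and color moments
alone are each provably incomplete while their concatenation separates all
four classes — verified by a nearest-centroid probe.  The **XOR feature
task** goes further: the label is the parity of signs carried by one LF and
one HF coordinate, so *no* linear head on either block or on their
concatenation can exceed 75% in expectation, while a small ReLU hidden
layer separates it — this isolates the qualitative claim that learned
nonlinear fusion beats both single-family classifiers and fixed linear
weighting.

None of these fixtures looks like tissue or skin: there are no stains, no
lesion geometry, no illumination or acquisition artifacts, and class
differences are globally stationary.  Passing tests therefore demonstrate
that the pipeline's mechanics and orderings behave as designed under the
statistical structure the method assumes, not that any particular accuracy
would be reached on real histology or dermoscopy data.

## Problem sizes and defaults

Training the full-width network (channels 32…256) is intended for the
full-size fixtures; the package's experiments and CI use the
**reduced-width profile** (`width_factor=0.25`, channels 8…64, 64-dim HF),
which preserves every spatial shape of the standard architecture.  The
fusion-ordering experiment uses the complementarity fixture at 32 images
per class (96×96, noise sd 10), `m=2` fractional crops per image, 18
epochs, initial lr 0.01, decay 0.9, batch 16 — sizes at which the ordering
is stable across seeds while a single experiment stays a few CPU-minutes.
The full-scale schedule (45 epochs) remains the `TrainConfig` default.
Unit tests use a 60-image noiseless profile (64×64) and a width-0.125
variant.

## Open choices, resolved

* The emulated protocol mentions both a single 7:1:2 split and 10-fold
  cross-validation without saying how they compose; the package provides
  both (`CNMPModel.fit` / `evaluate.cross_validate`) and defaults to the
  split.
* Whether the 2-class network reuses the 4-class architecture: it is rebuilt
  from scratch with `n_classes=2`; only the rasterize layer's output width
  changes.
* ROC positive class defaults to label 1 (the melanoma-like minority class),
  with a flag to flip.
* Texture/color features are computed per 140×140 patch and averaged per
  source image, mirroring the patch-averaged handling of HF.

## Known limitations

* CPU-only; a full-width, full-size training run is hours, not minutes.
* The synthetic generator's classes are globally stationary textures;
  methods that exploit spatial composition would not be distinguished.
* `MLPFusionModel` has a single hidden layer by design; deeper fusers are
  out of scope.
* Cross-device bit-reproducibility is not guaranteed (BLAS/FFT variation).
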