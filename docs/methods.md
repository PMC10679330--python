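# Methods

This note records the models implemented in `msgaug`, the defaults and why
they were chosen, the numerical conventions, and what the bundled synthetic
benchmark can and cannot show.

## Image convention

All in-memory images are `(N, H, W, 3)` float32 in [−1, 1] (the tanh range
generative models emit); labels are integers over named classes
(`LabeledImageSet`).  Conversion to 8-bit RGB happens only at PNG/TIFF I/O,
by the affine map [−1, 1] → [0, 255] with rounding; the reader inverts it.
Square power-of-two resolutions are required because the generator doubles
resolution per block.

## Synthetic texture benchmark

Real stained-patch collections are an external input; the bundled generator
supplies a class-separable stand-in.  Each class is defined by a base
colour, a Poisson mean number of coloured disks, a disk radius range, a
disk colour and a Gaussian pixel-noise sd (applied on the [−1, 1] scale).
Class 0 is a near-uniform bright class and class 1 a pale sparse one,
mimicking the two visually extreme categories of public colorectal patch
data (background and adipose); further classes sweep an HSV colour wheel
with densities drawn once per class from [8, 22].  Disk counts are Poisson
rather than fixed so that images within a class vary — without that, GAN
sample diversity would be unmeasurable.  Rendering is per-class seeded
(`SeedSequence([seed, 1, class_id])`), so datasets are bitwise reproducible
and class k's images do not depend on how many classes were requested.

What the benchmark does **not** emulate: nuclei, stain variation, spatial
autocorrelation beyond disk scale, class imbalance, label noise.  Passing
tests therefore demonstrate that the pipeline's mechanics (conditional
generation, confidence filtering, augmentation accounting, metrics) are
correct, not that augmentation improves accuracy on real histology.

## Neural-network engine

The package carries its own CPU-native engine: a small reverse-mode
autodiff core over numpy float32 arrays (`msgaug.nn`), with im2col
convolution, 2×2 average pooling, nearest-neighbour upsampling, leaky
ReLU/tanh, log-softmax, inverted dropout, SGD(+momentum) and Adam.
Gradients of every primitive are verified against central finite
differences in the test suite.  Scalar hyperparameters are cast to float32
inside the optimizers so parameters never drift to float64 (which would
break bitwise checkpoint roundtrips).  All computation is single-threaded
numpy and fully deterministic given seeds.

## MSG-GAN

* **Generator.** Block 0 projects the latent (default 256-dim, standard
  normal) to a 4×4 feature grid through a learned linear map; every
  subsequent block is nearest-neighbour 2× upsampling followed by two 3×3
  convolutions with leaky-ReLU slope 0.2.  Each block's features are mapped
  to RGB by a 1×1 convolution with tanh, giving one image per scale.
* **Discriminator.** Processes the pyramid top-down.  At each scale the
  incoming RGB image passes a 1×1 convolution (16 features); below the top
  scale those features are concatenated channel-wise with the pooled
  feature map from the previous block.  Two 3×3 convolutions per block,
  average-pool between scales, and a linear head on the 4×4 features yields
  one unbounded score per sample (hinge losses need no sigmoid).
* **Channel schedule.** `base_channels` (default 32) at 4×4, halved per
  resolution doubling, floor 16 — small enough for CPU training and
  configurable upward.
* **Real pyramids.** Real batches are reduced scale-by-scale with 2×2
  average pooling; the top level is the batch unchanged.
* **Losses.** Relativistic average hinge as in the README.  The public
  `discriminator_loss` / `generator_loss` evaluate in float64; the training
  path uses the equivalent differentiable float32 graph.
* **Training loop.** Per batch: one discriminator Adam step on (real batch,
  freshly generated fakes with the generator detached), then one generator
  Adam step on another fresh fake batch.  Adam uses (β1, β2) = (0, 0.99),
  the customary setting for multi-scale adversarial training; learning
  rates default to 1e-4 (G) and 4e-4 (D) — the two-time-scale rule.  One
  epoch is one shuffled pass over the class's images in batches of 8,
  dropping the final partial batch.  Non-finite losses abort with a
  diagnostic.  Omitted stabilisers (minibatch-stddev, pixel norm, weight
  averaging) are deliberate: the core multi-scale mechanism suffices at
  desk scale.
* **Sampling** takes only the top-resolution output, clipped to [−1, 1],
  and is seeded independently of training.

## Selection

"Class probability" means the probability the scoring classifier assigns to
the image's *intended* (conditioning) class — not the max over classes —
because the filter's purpose is to certify the label the image will carry.
The comparison is strictly greater than α; an image at exactly α is
dropped.  The scorer is the baseline classifier trained without any
augmentation and is never retrained afterwards.  Defaults: α = 0.85 (the
ablation optimum of the reference study); generated-to-original ratio 0.5
before selection.  Images filtered out are not regenerated; the pipeline
samples a fixed count per class and keeps what survives (callers wanting a
fixed post-selection count can oversample and truncate).

## Classifier

Backbone-agnostic head: FC(→256) → ReLU → dropout(0.5) → FC(→K) → softmax.
The bundled desk-scale backbone is four 3×3-conv blocks (16/32/64/64
channels, leaky-ReLU 0.1, 2×2 average pooling).  The hidden width 256 and
momentum are configurable; an adapter slot exists for user-supplied
GoogleNet/InceptionV3-style backbones whose pretrained weights are an
external concern.

The learning-rate scheme is recursive: lr_ep = lr_{ep−1} × [(1 +
cos(π·ep/epochs))/2 × (1 − lr_f) + lr_f], applied once per epoch with
ep = 1..epochs.  The factor lies in [lr_f, 1] and equals lr_f exactly at the
final epoch, so the compounded decay is much faster than non-recursive
cosine annealing (after 20 epochs with lr_f = 0.1 the rate has fallen by
~7 orders of magnitude).  The recursive form is implemented literally; a
non-recursive variant is *not* used.

Two optimisation presets coexist deliberately.  `ClassifierConfig` defaults
to SGD lr 0.001, momentum 0, 20 epochs, batch 64 — the fine-tuning regime
appropriate when a pretrained backbone is plugged in.  The pipeline's
desk-scale defaults are lr 0.01 with momentum 0.9, because a from-scratch
small CNN cannot make useful progress at the fine-tuning rate (train
accuracy stays near chance within the epoch budget, which would make the
selection stage vacuous); 0.01/0.9 brings the synthetic benchmark to ≥ 0.99
validation accuracy within five epochs.  This choice was made once, from
that optimisation-feasibility observation, and is configurable.

## Evaluation metrics

* **Feature extractors** are an interface: tests and desk runs use either
  identity features or raw image moments (per-channel mean and sd, gradient
  energy, off-diagonal colour covariance — 12 dims, no learned weights).
  Published-scale FID/KID magnitudes require a pretrained-network extractor,
  which users supply; absolute values from the raw-moment space are not
  comparable to published tables.
* **IS**: per split (default 10), exp of the mean KL between row
  distributions and the split marginal; bounded by [1, K].
* **FID**: ‖Δμ‖² + Tr(Σr + Σf − 2(ΣrΣf)^{1/2}) with unbiased (N−1)
  covariances; the cross term is computed as Tr((A Σf A)^{1/2}) with
  A = Σr^{1/2} via symmetric eigendecomposition, clamping negative
  eigenvalues at zero, so the argument stays PSD; the result is floored at
  0 against rounding.
* **KID**: the unbiased squared MMD with kernel (x·y/d + 1)³ (degree 3,
  1/d scaling); may legitimately be slightly negative; an optional
  block-averaged mode serves large N.
* **Classification metrics**: per class, precision TP/(TP+FP), recall
  TP/(TP+FN), specificity TN/(TN+FP) from the confusion matrix (rows =
  truth); degenerate denominators yield NaN markers, never exceptions;
  overall accuracy is trace/total.
* **Paired t-test**: t = mean(d)/(sd(d)/√n) with the (n−1) sd, two-sided p
  from Student's t with n−1 df; zero-variance differences return NaN.

## Pipeline and reproducibility

`run_full` executes, per seed: data preparation → baseline training →
per-class GAN training (sequential) → sampling → selection with the
baseline scorer → augmented training → evaluation of both models on the
byte-identical validation set; then a paired t-test of overall accuracy
across the seed list (NaN when fewer than two seeds or zero-variance
differences).  Every stage writes its artifacts (versioned `.npz`
checkpoints with JSON headers, CSV logs, PNGs, JSON reports) under the run
directory.  All randomness descends from the run seed through
`SeedSequence` spawning with fixed stage tags, so repeated runs are
reproducible down to PNG bytes.

Desk-scale problem sizes used by the acceptance script and the end-to-end
tests: 3 classes, 100 train + 40 validation images per class at 32×32,
depth-4 GANs trained 30 epochs, 200 generated images per class, classifier
retrained 10 epochs.  These sizes keep a full comparison to a few CPU
minutes while leaving every stage non-degenerate.

## Known limitations

* Accuracy on the synthetic benchmark is often saturated (near 1.0) for
  both baseline and augmented models, so the across-seed t-test frequently
  returns its NaN marker; the benchmark exercises mechanics, not effect
  sizes.
* The per-class GAN occasionally converges poorly on the near-uniform
  bright class (its samples then fail selection) — mirroring, at toy scale,
  the reference observation that background-like classes are the hardest to
  model.
* No progressive fade-in, no comparison generator families, no t-SNE
  visualisation, no pretrained feature extractors are included.
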