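# Methods

## Problem and scope

`akscreen` implements a binary dermoscopy-image classifier for the
clinically confusable pair *actinic keratosis* (AK — precancerous, the
positive class) versus *benign keratosis* (BK), together with the classical
pipeline it is benchmarked against and the evaluation protocol that compares
them. The package is exercised end to end on synthetic lesion-like images,
so every stage is testable without downloading any clinical archive; real
data in the HAM10000 metadata dialect (`image_id,dx` CSV plus image files,
`akiec`/`bkl` diagnosis codes) plugs into the same manifest loader.

## Synthetic data generator

The generator emulates the two cues that distinguish the classes in real
dermoscopy — surface texture and lesion erythema — on a skin-toned
background:

* an oriented sinusoidal grating (random orientation and phase per image)
  whose spatial frequency is `3 + 7·separation` cycles per image side for
  the positive class and 3 for the negative class, amplitude 18 of 255;
* a soft-edged random ellipse (the lesion), darkened by 25 units, whose color
  shifts with `separation`: toward red for AK-like images, toward
  yellow-brown for BK-like images;
* i.i.d. Gaussian pixel noise (default sd 8), then clipping to 8-bit.

`separation` in [0, 1] controls class separability; at 0 the two
class-conditional distributions are *identical*, giving an exact
chance-level negative control. Defaults are 200 images per class at
64 × 64 — large enough that held-out metrics are stable, small enough that
the full benchmark runs in CPU minutes. Each image draws from its own
`(seed, class, index)`-keyed random substream, so datasets are pure
functions of their configuration and enlarging `n_per_class` never changes
earlier images.

What the generator deliberately does **not** model: hair and ruler
artifacts, specular highlights, vignetting, camera color variation, and the
intra-class heterogeneity of real lesions. Passing tests on synthetic data
therefore demonstrate that the pipeline's mechanics (preprocessing,
optimization, evaluation) are correct and that the models can exploit
texture-frequency and color signals — not that real-image accuracies are
reproduced.

## Preprocessing chain

Fixed order: **augment → histogram equalization → RGB→CIELAB → resize/scale**.

* *Augmentation* expands each selected source image to exactly 4 samples:
  the original, its 90° rotation, horizontal flip, and vertical flip,
  with deterministic identifier suffixes (`__rot90`, `__hflip`, `__vflip`)
  so provenance is always traceable. By default only the minority class (by
  count) is expanded — on a balanced dataset there is no minority and the
  step is a no-op. With a typical 327-AK/1099-BK archive subset this yields
  1308 AK samples, approximately balancing the classes.
* *Histogram equalization* uses the classic CDF remap
  `round((cdf(v) − cdf_min) / (n − cdf_min) · 255)`, which leaves an already
  uniform histogram exactly fixed. Default mode equalizes each RGB channel
  independently; a `luminance_only` mode equalizes Rec.601 luma and rescales
  chroma proportionally. The channel policy is a configuration field because
  either convention is defensible.
* *CIELAB conversion* uses the standard sRGB/D65 transform
  (scikit-image). Lab separates lightness from chroma, which makes the color
  cue explicit. The CNN consumes Lab by default; an RGB input mode exists
  because a deployed classifier may receive plain RGB frames, and both paths
  must behave identically apart from the channel encoding.
* *Standardization* bilinearly resizes to 64 × 64 and maps channels to
  [0, 1] by fixed affine ranges (L/100, (a+128)/255, (b+128)/255 for Lab;
  v/255 for RGB).

Everything in this chain is deterministic; the only randomness in the whole
system sits in the generator, weight init, batch shuffling, dropout masks,
and fold assignment — all seeded.

## The shallow CNN

Architecture (64 × 64 × 3 input): conv 6@5×5 (stride 1, pad 2) → LeakyReLU
(slope 0.01) → maxpool 2×2/2 → conv 16@5×5 → LeakyReLU → flatten (16 384)
→ dense 120 → LeakyReLU → dropout 0.5 → dense 2 → softmax. One pooling
layer only, after the first convolution. Parameter count with the default
120-unit hidden layer: 456 + 2 416 + 1 966 200 + 242 = 1 969 314.

Training: classical momentum SGD (momentum 0.9, learning rate 1e-4 fixed,
mini-batches of 10 in seeded shuffled order, final partial batch kept), L2
weight decay 5e-4 applied to weights but not biases, softmax cross-entropy.
Dropout is inverted (activations scaled by 1/(1−p) during training), so
inference is exactly dropout-free. Default 30 epochs: on the synthetic
study task training converges well before that, and 30 epochs keeps a full
10-fold run in single-CPU minutes.

The hidden width (120), epoch count and loss are deliberate package
defaults, not established constants of the problem; they are exposed as
parameters. Weight init is seeded uniform fan-in (limit √(6/fan_in)) with a
0.1 gain on the final classification layer, chosen so a freshly built
network predicts near-uniform probabilities and the first-epoch loss starts
at ≈ ln 2 on balanced data — a useful sanity invariant and a mild
optimization aid.

The implementation is plain NumPy (im2col convolutions lowered to BLAS
matmuls, float32), which keeps training bit-reproducible from
`(init_seed, shuffle_seed, data)` on a fixed platform and makes the
backward pass directly verifiable: the test suite checks analytic gradients
of every layer against central finite differences on a scaled-down
configuration.

## HOG + classical baselines

The traditional pipeline resizes to 200 × 200, converts to Rec.601
grayscale, and computes a histogram-of-oriented-gradients descriptor with
32 × 32-pixel cells, 2 × 2-cell blocks at 1-cell stride and 9 unsigned
orientation bins: 6 × 6 whole cells (floor tiling; the 8-pixel right/bottom
margin is excluded), 5 × 5 block positions, 25 · 4 · 9 = **900**
dimensions. The bin count, stride and normalization are forced by that
dimensionality: 900 = 5·5·2·2·B requires B = 9, and only a 1-cell stride
yields 5 × 5 blocks from 6 × 6 cells.

Numerical conventions (all fixed so the descriptor is reproducible):
central-difference gradients with one-sided differences at borders,
orientation bin centers at (k+½)·20° with linear magnitude interpolation
between the two nearest bins (wrapping at 180°), block L2 normalization
v/√(‖v‖² + ε²) with ε = 1e-6 (a constant image maps to the zero vector).
HOG runs on the *original* image by default, independent of the CNN's
equalization/Lab chain, since the two pipelines are separate contenders.

Classifiers: SVM (RBF, C = 1), random forest (100 trees), k-NN (k = 5) —
conventional defaults, overridable, with optional seeded grid-search
tuning. Scores for ROC analysis are the SVM decision value, the forest's
positive-vote fraction, and the positive-neighbor fraction respectively.

## Evaluation protocol

Stratified 10-fold cross-validation (stratification is a package default —
the safer convention for imbalanced data — and switchable). Per fold the
model factory produces a *fresh* estimator, fitted on the training split
and scored on the held-out split; reported values are per-fold metrics and
their arithmetic means. Class predictions use the estimator's own decision
rule (the 0.5 probability threshold for probabilistic models, the sign of
the decision value for the SVM).

Augmentation, when enabled, happens **inside** each fold on the training
split only. The alternative — augmenting before splitting — leaks
near-duplicates of test images into training and inflates every metric;
the harness records identifier provenance per fold so the absence of
leakage is machine-checkable, and the leaking order is intentionally not
offered.

Metrics: Acc, Sens, Spec, Prec and MCC from the confusion counts, with any
zero-denominator metric reported as NaN plus a warning flag rather than a
silent 0; AUC by threshold sweep with tie grouping and trapezoidal
integration, which equals the tie-corrected Mann–Whitney statistic (a test
asserts agreement to 1e-10). Wall-clock training time is logged and stored
in the JSON report but never asserted and excluded from the deterministic
CSV report, since it is hardware noise.

## Determinism and seeds

A single run seed feeds `numpy.random.SeedSequence`, which derives
independent sub-seeds (all < 2³¹) for data generation, fold assignment,
weight init, shuffling/dropout, and baseline randomness. Identical run
configurations therefore produce byte-identical metric reports; the test
suite asserts this end to end.

## Problem sizes used in the shipped checks

The separability checks run at 200 images per class with full separation
(10-fold CV for the CNN at 30 epochs and for HOG+SVM) and at zero
separation for the chance-level control (half/half train/test split).
These sizes were chosen as the smallest at which held-out metrics are
stable enough to assert; they are the package's declared study conditions,
not tuned values.

## Known limitations

* Real-archive performance is *not* asserted anywhere: reproducing
  published accuracies requires the original images plus several unstated
  protocol details (fold stratification, augmentation/split order, epoch
  budget, hidden width), so the package bounds itself to structural
  contracts and synthetic-task behavior.
* The NumPy CNN is single-threaded-BLAS fast, not GPU fast; it is sized for
  64 × 64 inputs and two conv stages, and is not a general deep-learning
  framework.
* Bit-level determinism holds for a fixed platform/BLAS; across different
  BLAS builds results may differ in the last float digits.
* `luminance_only` equalization clips saturated chroma after rescaling;
  hue is preserved only up to that clipping.
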