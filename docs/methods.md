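# Methods

## Problem and scope

The package classifies endoscopic tympanic-membrane images into four
diagnoses — normal, otitis media with effusion (OME), chronic otitis media
(COM), and cholesteatoma — and verifies the classifier visually with
Grad-CAM. Clinical image archives cannot be redistributed, so the package
ships a synthetic phantom generator that emulates the geometry and
colorimetry of endoscope captures; every statistical claim the test suite
makes is about this synthetic family, not about clinical data.

## Preprocessing

Raw captures are a bright circular field on a black margin. Margin removal
finds the tightest axis-aligned box around pixels whose max-channel
intensity exceeds a threshold (default 10/255); an all-dark frame keeps the
full box and warns rather than raising, since a degenerate capture should
surface downstream as a data problem, not a crash. The crop is resized
bilinearly to a square working resolution (default 270) with values scaled
to [0, 1]. No channel-wise standardisation is applied by default — the
networks start with batch normalisation, which absorbs affine input shifts
— but a per-channel mode exists in `normalize`.

Training augmentation composes, in order: optional horizontal mirror,
optional vertical mirror, rotation by k·90°, and a random crop to the patch
size (default 256 from 270, i.e. 15×15 valid offsets per axis). Rotations
are restricted to quarter-turns so no fill pixels are ever invented; the
(flip, flip, k) triple double-covers the dihedral group of the square, so
each of its 8 elements occurs with probability 1/8. Evaluation uses the
deterministic centre crop.

## Architecture

Backbones are the standard 18-layer (basic-block) and 50-layer
(bottleneck) residual networks with a global-average-pool + linear head.
An attention block — none, CBAM, or the shuffle module — is appended to the
output of every residual block. With 4-class heads the trainable-parameter
counts are:

| variant            | exact      | truncated M |
|--------------------|------------|-------------|
| resnet18           | 11,178,564 | 11 |
| resnet18 + shuffle | 13,963,844 | 13 |
| resnet18 + CBAM    | 11,266,396 | 11 |
| resnet50           | 23,516,228 | 23 |
| resnet50 + CBAM    | 26,032,756 | 26 |

Truncation (integer division by 10⁶, not rounding) is the reporting
convention: 13,963,844 prints as 13 M.

The shuffle gate's 1×1 compression convolution (4C → C) carries no bias, so
the per-network overhead is exactly `Σ 4C²` over gated block widths
(2,785,280 for ResNet18). The gate value at zero weights is sigmoid(0) =
0.5 regardless. CBAM follows the published module: a shared two-layer
bottleneck (reduction 16, bias-free) over average- and max-pooled channel
descriptors, then a 7×7 spatial convolution (with bias) over the
cross-channel mean and max maps. Attention placement per block, the
bias-free compression, and reduction 16 are the combination under which the
published parameter column reproduces cell for cell; none of the three is
stated explicitly by the source architecture description.

Shuffle attention requires even spatial dimensions at every gated block;
with the standard stem (7×7/2 conv + 3×3/2 max-pool) this holds for any
input side divisible by 32 and at least 64.

## The NumPy engine

No autodiff framework is a dependency: `otoshuffle.nn` is a small
reverse-mode engine over float32 NumPy arrays (conv via im2col, batch
normalisation with running statistics, max/avg pooling, the
space-to-depth pair, nearest-neighbour upsampling, fused softmax
cross-entropy; SGD-with-momentum and Adam optimisers). Gradients are
accumulated on every node of the graph, which lets Grad-CAM read the
gradient of an internal feature map without a hook mechanism. All gradient
paths are tested against central finite differences. Determinism: every
stochastic choice flows from a master seed through named SeedSequence
streams (`derive_seed(seed, "init" | "shuffle" | "augment" | ...)`), and
the engine itself is single-threaded apart from BLAS matmuls, so repeated
runs are bit-identical on a given platform.

## Synthetic phantoms

Each phantom is a 640×480 frame: black margin, a bright radially shaded
circular field (radius 170–205 px, jittered centre), a pearly
tympanic-membrane disk with a malleus-handle streak and a light reflex, and
one class cue matching the diagnostic criterion:

* OME — amber tint gradient over the intact membrane (denser inferiorly);
* COM — an irregular dark perforation with a pale thickened rim;
* cholesteatoma — a superior-quadrant (attic) erosion blob with white
  keratin-debris speckle.

Gaussian sensor noise (sd 3/255 by default) is added inside the field only,
so the margin stays exactly black and margin removal is well defined. The
default class mix follows the reported clinical prevalence
(1180/400/627/165, normalised by their sum), with a balanced alternative
mirroring the curated 71-case test set (19/17/17/18). Rendering the same
sub-seed under two labels yields frames identical except for the lesion,
which the localization tests exploit.

What the phantoms do **not** model: specular highlights and wax, anatomical
variation of the malleus and annulus, otorrhea, real color statistics of
inflamed mucosa, camera optics. Passing tests therefore demonstrate that
the pipeline is wired correctly and that the architecture can learn
localized and colorimetric cues — not clinical performance.

## Training and evaluation protocol

The estimator (`OtoscopyClassifier`) minimises cross-entropy with Adam
(default lr 1e-3) or SGD; inverse-frequency class weighting is available
for the imbalanced prevalence mix but off by default. Evaluation follows
the fixed-test-set + stratified k-fold scheme: the held-out test ids never
enter any fold, and with k = 5 each session trains on 4 folds and validates
on 1 (the 8:2 split). Folds are stratified by diagnosis because the rarest
class is ~7% of the data; fold aggregate accuracy is reported as mean ±
sample standard deviation (ddof = 1), to three decimals. (The source
protocol reports 473 validation images per fold where 2201/5 ≈ 440; the 8:2
rule as stated is what is implemented.)

Assistive-study statistics summarise two-pass reader records: per-reader
accuracy before/after advice, the delta decomposed as corrected-minus-newly-
wrong, the pooled correction rate among initially wrong answers, and the
compliance rate among answers that disagreed with the advice. A simulator
(per-reader error rate, Bernoulli compliance) generates records for
parameter-recovery tests.

## Problem sizes used by the test suite

The synthetic study trains resnet18+shuffle on 800 phantoms and evaluates
on 200, with frames standardised to 72 px and trained on 64-px patches —
the smallest resolution at which every gated block keeps even spatial
dimensions. These sizes are the package's chosen study conditions for the
synthetic family; the library defaults (270/256) remain those of the
full-resolution protocol. In the small-data cross-validation regime
(100-image training folds) a batch size of 8 is used: with larger batches
an epoch has too few update steps and the optimiser can stall in a poor
basin on some initialisations. The lesion-localization check trains a small
three-conv network (16×16 final map) on paired normal/COM phantoms, because
the resnet's 2×2 final map at the reduced input resolution cannot resolve
lesion position; localization is asserted with a paired one-sided t-test of
Grad-CAM mass inside vs outside the lesion bounding box over 20 held-out
perforation phantoms.

## Numerical choices and edge cases

* Grad-CAM applies ReLU before max-normalisation; an identically zero map
  is returned as zeros with a warning rather than renormalised.
* Overlay blends `(1-α)·image + α·m·colormap(m)`, so a zero map yields the
  dimmed image exactly and α = 0 the original.
* Bilinear resizing uses anti-aliasing only when downsampling; an identity
  resize preserves values exactly.
* Max pooling pads with −∞ so border windows never select padding.
* Batch-norm running variance uses the unbiased correction, momentum 0.1.
* `softmax_cross_entropy` normalises by summed sample weight, so uniform
  weights reproduce the plain mean.

## Known limitations

Single-threaded CPU training limits practical input resolution; there is no
pretrained-weight support (the source work does not state any); arbitrary-
angle rotation augmentation is deliberately unsupported; phantom realism is
intentionally minimal, so accuracy numbers on phantoms say nothing about
clinical accuracy.
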