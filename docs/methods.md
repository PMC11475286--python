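# Methods

## Problem and pipeline

`pectseg` segments mediolateral-oblique (MLO) mammograms into three
classes — background (0), breast tissue (1) and pectoral muscle (2) —
so that downstream lesion analysis can operate on breast tissue alone.
The pectoral muscle appears in MLO views as a bright corner wedge whose
intensity profile interferes with tissue analysis; burned-in
annotations (machine labels, radiologist marks) form a fourth de facto
class that the preprocessing stage removes.

The pipeline is: preprocessing (annotation removal, breast isolation,
VOI-LUT contrast) → class-weight computation → affine augmentation →
encoder/ASPP/decoder training with SGDM → per-class validation.

## Preprocessing

An input image is binarized (`B(I) = {f(p) | p ∈ I}` with `f(p) = 1` on
foreground), its 4-connected islands `{I_1, …, I_n}` are labelled, and
the breast is selected as `S = argmax_k area(I_k)` — the assumption
being that the breast together with its attached muscle wedge is always
the largest island. Every other island is zeroed and exported to a CSV
metadata record (id, area, bounding box, mean intensity) so removed
annotation content remains auditable.

Numerical/policy choices:

- **Threshold policy.** Default Otsu (maximizes between-class variance);
  a fixed threshold is available as an override. A constant image under
  Otsu yields an all-zero mask with a warning instead of aborting batch
  runs.
- **Tie-break** for equal-area maximal islands: lowest island label,
  i.e. raster-scan order — deterministic and documented.
- **VOI LUT.** Linear DICOM-style windowing
  `y = clip((x − (c − ½))/(w − 1) + ½, 0, 1) · max_out`; when no window
  is present the fallback is a full-range linear min–max window. The
  mapping is monotonically non-decreasing by construction.
- **Stage order.** Masking → breast segmentation → contrast enhancement
  by default; `enhance_first=True` switches the order (both orders
  produce the same three-class restructuring, so this is exposed as
  configuration rather than fixed).
- Coordinates are row-major, 0-based, origin top-left.

## Class-imbalance weighting

Background ≫ breast ≫ muscle in pixel count, so an unweighted pixel
loss underserves the clinically critical muscle class. For a binary
segmented-region problem with inside/outside pixel counts `Y+`/`Y−`,
the weighted cross-entropy for a pixel with score `x` is

    L = −α·log(1 − σ(x))   if y = 0,
    L = −β·log(σ(x))       if y = 1,

with `α = λ·Y+/(Y+ + Y−)` and `β = Y−/(Y+ + Y−)`. Each side is weighted
by the *other* side's frequency — the rare positive class receives the
large weight — and the tuning factor λ scales the prevalent (outside)
side. We implement the standard negated (non-negative) cross-entropy;
σ and probabilities are clamped to `[1e−7, 1 − 1e−7]` so saturated
predictions give a large finite loss.

**Three-class bridge.** Applying the formula one-vs-rest gives each
class k the complement-frequency weight `w_k = 1 − f_k`, with the
background class (the "outside the segmented regions" side that α
weights) additionally scaled by λ, and the vector normalized to sum to
the number of classes. For two classes the un-normalized vector is
exactly `(α, β)`; for balanced data at λ = 1 the loss reduces to
unweighted cross-entropy. λ defaults to 1 (config key `loss.lambda`);
note that because normalization cancels any uniform scaling, λ acts
only through the background/foreground balance.

**Combined objective.** The total loss is a sum of a classification
term and a segmentation term, `L(W) = L_class + L_seg`. The
classification term is implemented as the image-mean of the pixel loss,
which for equal-sized images duplicates the segmentation term; a config
flag (`include_classification_term`) disables the duplicate. The
duplication only rescales gradients, so results are insensitive to the
flag up to a learning-rate factor of 2.

## Augmentation

Random affine transforms — translation up to 10 px per axis, rotation
uniform in [−30°, +30°], scale uniform in [0.9, 1.1] (bounds for scale
are a package choice; only "scale" is prescribed) — are applied
identically to image (bilinear) and mask (nearest-neighbour, so labels
stay in {0,1,2}); out-of-frame regions fill with class 0 / intensity 0.
Each copy draws a *single* transform type, cycling
translation/rotation/scale, so 3 copies per source quadruple a dataset
(322 → 1288); composed transforms are available via `compose=True`.
Per-item provenance (source id, dx, dy, θ, scale) is logged and replays
exactly. Augmentation is applied after preprocessing, so stripped
artifacts are never re-introduced, and after source-level splitting, so
augmented siblings cannot leak across splits.

## Network and training

The model follows the DeepLab-v3+ pattern with a residual-bottleneck
encoder: a 7×7/stride-2 stem, 3×3/stride-2 max pool, and four stages of
1×1→3×3→1×1 bottlenecks with projection shortcuts. The full-scale
preset uses stage repeats (3,4,6,3) and 64 base filters — 49 main-path
convolutions ahead of the pixel-classification head; the `tiny` preset
keeps the identical block topology at repeats (1,1,1,1) and 8 base
filters. The final stage trades stride for dilation 2 (output stride
16), where an ASPP module (1×1 branch, three dilated 3×3 branches, a
global-pool branch, 1×1 projection) aggregates multi-scale context. The
decoder upsamples ASPP output to stride 4, fuses it with projected
low-level features through two 3×3 convolutions, upsamples to full
resolution, and applies a refinement 3×3 convolution over the decoder
features concatenated with the raw input intensities — restoring the
pixel-level intensity cue that strided encoding blurs — before a 1×1
classifier and per-pixel softmax over the 3 classes.

The engine is pure NumPy (float32, NCHW): convolution as a GEMM over an
im2col patch tensor, batch normalization with running statistics
(momentum 0.1, eps 1e−5), bilinear upsampling as separable
interpolation matrices. Backward passes were verified against central
finite differences. ImageNet pretraining is not supported; training is
from He-normal initialization (the `pretrained` flag exists and errors
if set, so the limitation is explicit).

Optimization is stochastic gradient descent with momentum,

    v_{t+1} = μ·v_t − η·∇L(W_t),      W_{t+1} = W_t + v_{t+1},

with defaults η = 0.001, 50 epochs, mini-batch 2; μ is not prescribed
anywhere and defaults to 0.9. All randomness (init, shuffling,
augmentation, splits) funnels through seeded NumPy generators recorded
in the run manifest; repeated runs on the same hardware are
bit-identical. Splits use nearest-integer rounding for train and
validation with the remainder as test — the policy that maps 1288 items
at 70/20/10 onto (902, 258, 128). Class weights are computed from the
training split only. The per-epoch history records mean loss and pixel
accuracy for training and validation; the weights with the best
validation accuracy are restored at the end. Non-finite loss aborts
with a diagnostic.

## Validation

Per class k with predicted/truth pixel sets `P_k`, `G_k`:
`D = 2|P_k∩G_k|/(|P_k|+|G_k|)` and `J = |P_k∩G_k|/|P_k∪G_k|`
(so `J = D/(2−D)` identically). When a class is absent from both masks
the score is 1; absent from exactly one, 0 — keeping per-class averages
defined on images lacking a class. The confusion matrix is normalized
by the grand pixel total (not row-wise), so its diagonal sum equals
overall pixel accuracy. CDF summaries are right-continuous empirical
distributions; threshold tables report the percentage of images at or
above each threshold (default grid 0.6–0.95). Area-error rows sum
per-class pixel areas over a collection; the absolute error is
`|predicted − truth|` and the relative error divides by the
ground-truth (radiologist) area, reported to 3 decimals.

## Phantom generator

The generator emulates the geometric and intensity structure the
pipeline depends on: a breast modelled as a half-ellipse pressed
against the chest-wall edge, a pectoral wedge as a right triangle
(vertical:horizontal leg ratio 1.6) anchored in the adjacent corner and
overlapping the ellipse, small bright disks planted in the background
as annotation artifacts, and per-class intensity means with additive
Gaussian noise, ordered muscle > breast > background (defaults 200 /
120 / 30 on an 8-bit scale, noise σ = 8, artifact intensity 245 —
free parameters chosen to give clear but non-trivial class contrast).
Default class fractions are breast 0.60, muscle 0.08, background 0.32,
the pixel budget of a typical MLO frame. The wedge legs are solved
analytically from the muscle fraction and the breast semi-axis by
bisection on the rasterized ellipse, so emitted proportions track the
request to within discretization error (±1 pp at 512×512); unreachable
geometry raises an explicit error. A master seed plus per-item counter
(`default_rng((master, i))`) makes every dataset item independently
reproducible.

What the phantom does *not* model: anatomical texture, breast-density
classes, lesions/microcalcifications, scanner artifacts other than
bright markers, and the intensity overlap between fibroglandular tissue
and muscle found in real mammograms. Passing the learning study on
phantoms therefore demonstrates that the pipeline's machinery (loss
weighting, geometry handling, optimization, evaluation) is correct —
not that the trained weights transfer to clinical images.

## Desk-scale study conditions

The scaled-down learning study (tests and `scripts/acceptance.py`) uses
96 phantoms at 96×96 px, the tiny backbone, 12 epochs, batch 4,
learning rate 0.05, momentum 0.9, split 70/20/10, class weights at
λ = 1. The higher learning rate and small epoch budget are the
appropriate optimization scale for a from-scratch tiny model on a small
synthetic set; the paper-scale defaults (256×256, η = 0.001, 50 epochs,
batch 2) remain the package defaults. Under these conditions held-out
per-class Dice exceeds 0.99 for all three classes, and median muscle
Dice with class weighting is not below unweighted training (three
seeds).

## Known limitations

- The NumPy engine is CPU-only and single-threaded beyond BLAS; the
  full-scale backbone is buildable and runs forward, but training it at
  256×256 is impractical here — the tiny preset is the supported
  training configuration.
- Batch normalization uses batch statistics in training mode, so very
  small batches give noisy normalization early in training; running
  statistics need a few epochs to settle before validation accuracy is
  meaningful.
- λ's effect is limited to the background-vs-foreground balance after
  weight normalization (see above); it is exposed for completeness
  rather than as a strong tuning axis.
- The DICOM writer emits a minimal secondary-capture dataset intended
  for exercising the reader, not a clinically conformant file.
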