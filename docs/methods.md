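# Methods

## Problem and overall design

`pdacwsi` implements a two-stage pipeline for detecting pancreatic ductal
adenocarcinoma (PDAC) in whole-slide histology images (WSIs). A WSI is far
too large for a single network input, so the pipeline works at two levels:

1. **Patch level.** The slide is cut into 1,024 × 1,024 px patches, each
   classified as *normal* vs *carcinoma* by a CNN ending in a global
   average pooling layer, a fully connected layer of 1,024 neurons and a
   two-way softmax. Training uses Adam (learning rate 10⁻³), categorical
   cross-entropy, batch size 8, random weight initialisation, and keeps
   the checkpoint with the highest validation accuracy (earliest epoch on
   ties). The default schedule is 100 epochs; desk-scale runs use far
   fewer because the synthetic task converges within the first epochs.
2. **Slide (WSI) level.** The per-patch tumor probabilities form a
   *malignant-probability heatmap* over the slide grid. Thirty-six summary
   statistics of that heatmap (below) feed a LightGBM gradient-boosted
   tree classifier that emits the slide-level cancer probability.

A separate U-Net branch performs pixel-level segmentation of tumor
regions, and Grad-CAM renders the classifier's attention for qualitative
comparison with the segmentation output.

## The 36 heatmap statistics

For counted heatmap cells with probabilities (p_normal, p_tumor):

* f1–f9: mean, variance, standard deviation, median, mode, minimum,
  maximum, range and sum of the normal probabilities; f10–f18: the same
  statistics of the tumor probabilities.
* f19–f34: patch counts N_p per class over eight half-open bands
  partitioning (0.5, 1]: P > 0.999, 0.99 < P ≤ 0.999, 0.95 < P ≤ 0.99,
  0.9 < P ≤ 0.95, 0.8 < P ≤ 0.9, 0.7 < P ≤ 0.8, 0.6 < P ≤ 0.7 and
  0.5 < P ≤ 0.6. Boundaries belong to the lower band; the top band is
  strictly greater than 0.999.
* f35: numeric label (0 = normal, 1 = tumor) of the class with the larger
  mean probability; f36: the label of the class winning the per-cell
  argmax count.

Design choices the definition leaves open, resolved once here:

* **Mode of a continuous sample** is taken after rounding to 2 decimals,
  most-frequent value, ties to the smallest value.
* **Ties in f35/f36** break toward tumor: a screening pipeline should err
  toward sensitivity.
* **Background cells** (patches that are > 80 % near-white, all channels
  > 220) are excluded from the statistics by default — white borders would
  otherwise swamp the slide summary. An `include_background` flag exists
  for ablation. Background cells render at probability 0 in the heatmap
  images, consistent with treating background as "not cancer".

## Heatmap geometry and rendering

Slide-level inference tiles with stride = patch size (non-overlapping),
which gives the blocky heatmap its grid. Probabilities map linearly per
channel from dark blue (0, 0, 139) at P = 0 to crimson (220, 20, 60) at
P = 1; overlays blend `(1 − α)·slide + α·heatmap` with α = 0.5 by default.
Coordinates are 0-based, y-down, with half-open patch windows
[x, x+size) — stated once so every module shares the convention.

## Half-overlap subsampling

Segmentation operates on 256 × 256 tiles cut from 1,024 px patches at
stride 128 (half the tile side). Offsets run over {0, 128, …, 896}² — an
8 × 8 grid, hence 64 tiles per patch. Tiles at the last offset overhang the
patch by 128 px and are completed by mirror (symmetric) padding; the
overhanging regions are cropped again before stitched averaging, so
stitching a constant image reproduces it exactly. Stitched probability at
a pixel is the mean of all tile predictions covering it.

## U-Net and the dice loss

The U-Net uses 'same' convolutions throughout, so each tile's output
probability map has exactly the tile's spatial size — the property that
makes half-overlap stitching line up without cropping network output.
Defaults are depth 4 / 64 base filters; the desk-scale preset (depth 2,
8 base filters, ≈33 k parameters) trains in minutes on one CPU and is what
the tests and the acceptance run use.

The training loss is the soft dice loss in its two-class form: the mean of
(1 − dice) over the tumor channel and the background channel. The
single-channel form has a degenerate optimum — predicting tumor everywhere
scores 2f/(1+f) on a mask with foreground fraction f, which is hard to
escape on majority-foreground tiles — and the background term removes it.
A smoothing ε = 1.0 stabilises training on empty masks; reported
evaluation dice is the plain tumor-channel statistic with ε = 0 (two empty
masks count as perfect agreement). Augmentation is random horizontal
flips (applied to image and mask) and a per-channel brightness scale
uniform in ±10 % (image only).

Training tiles are sampled preferentially from tiles that straddle the
lesion boundary (tumor fraction in (0.05, 0.95)): pure-background and
pure-tumor tiles carry almost no gradient signal for this task.

## Grad-CAM

Attention maps target the last convolutional layer of the backbone (the
usual convention). Channel weights are the spatial means of the
class-score gradients at that layer; the map is the rectified weighted sum
of activations, bilinearly upsampled to the patch resolution and min-max
normalised (an all-zero map stays all-zero).

## The numpy network engine

No deep-learning framework is part of the dependency set; the layers the
pipeline needs (3 × 3 'same' convolutions, max/global-average pooling,
dense layers, ReLU/sigmoid, softmax cross-entropy, nearest-neighbour
upsampling, Adam) are implemented directly on numpy with manual
backpropagation. Convolutions are computed as k² shifted matrix products,
which keeps peak memory at one padded input copy. Every gradient path is
verified against central finite differences in the test suite (with
smooth activations, since ReLU kinks make one-sided numerical estimates
unreliable). All randomness flows through `numpy.random.Generator`
instances seeded from a single integer, so runs are bit-reproducible on a
fixed platform in single-threaded mode.

Two backbone presets exist for the patch classifier: `small_cnn`
(4 conv blocks, ≈93 k parameters, native 256 px input — the desk-scale
model used throughout the tests) and `large_cnn` (a deeper plain-CNN
preset for larger experiments). Inputs are normalised per channel to
[−1, 1]; 1,024 px patches are downscaled to the backbone's native input
size by exact block averaging.

## Synthetic slides

Real gigapixel H&E slides cannot ship with the package, so the generator
emulates the two appearances the pipeline must separate:

* **tumor texture** — dense dark blobs ("nuclei", 25 per 10⁴ px²,
  radius 3–7 px, dark purple on mauve);
* **normal texture** — sparse pale blobs (6 per 10⁴ px², radius 2–5 px,
  pale pink on light pink);

plus per-channel Gaussian intensity jitter. Tumor regions are random
star-shaped simple polygons (sorted angles, perturbed radii at 15–25 % of
the slide side), standing in for free-hand lesion annotations; they both
delimit the tumor texture and provide the segmentation ground truth via
center-in-polygon rasterization. The default canvas is 4,096 × 4,096 px so
one slide yields a 4 × 4 grid of 1,024 px patches — the smallest grid on
which all 36 heatmap statistics are non-degenerate.

The two textures separate by far more than 3 pooled standard deviations in
mean patch intensity (asserted in the tests), so a small CNN can learn the
task quickly. That is deliberate — the generator validates the *plumbing*
and the *statistics*, not histological difficulty. Passing on synthetic
slides shows the pipeline is correctly assembled and learnable end to end;
it says nothing about performance on real H&E tissue, where class textures
overlap, staining varies, and lesions are not polygonal.

## Patch labelling and class balancing

Patches inherit labels from the polygon mask: tumor fraction ≥ 0.5 →
carcinoma, ≤ 0.05 → normal, otherwise unlabeled (excluded from training).
Split assignment happens at the parent-patch level *before* augmentation,
so no augmented copy of a patch can leak into a different split; the
class-balancing manifest then augments each class up to a per-split target
with rotations (90°/180°/270°) and flips, at most 6 variants per parent.

## The end-to-end synthetic study

The acceptance-scale run uses 24 slides (12 normal, 12 cancerous with 2
tumor regions each): 12 slides train the models, 12 are held out for
slide-level evaluation. Within the training half the booster's features
default to 2-fold cross-fitting — each half's heatmaps are predicted by
the CNN trained on the other half — so the booster never trains on
self-predicted, over-confident heatmaps; `cross_fit=False` reproduces the
simpler shared-training-set scheme. Held-out slides' heatmaps average the
two fold models' probabilities.

The segmentation branch trains on 8 tiles from each of up to 2
boundary-containing patches per cancerous training slide (≈96 tiles,
8 epochs, batch 4) and is evaluated by pooled dice of stitched,
0.5-thresholded patch predictions against the rasterized polygon truth on
4 held-out patches. These problem sizes are the package's chosen
desk-scale defaults; the generator's texture parameters and the study
design (counts, splits, thresholds) are fixed independently of any
particular run's outcome.

## Booster defaults

LightGBM defaults are pinned for reproducibility: 100 trees, 31 leaves,
learning rate 0.1, deterministic single-threaded fitting. One departure
from upstream defaults: `min_child_samples = 2` (upstream 20), because at
desk-scale slide counts (tens of slides) the upstream value forbids any
split at all. Feature importances are reported as total split gain, sorted
descending with ties broken by feature index.

## Known limitations

* The synthetic task is intentionally easy; accuracy/dice numbers on it
  are upper bounds of plumbing correctness, not clinical performance.
* The numpy engine is single-process and unsuited to training at the
  25-million-parameter scale of production backbones.
* `metrics` with zero denominators are reported as missing, never 0 — a
  downstream consumer must handle `null` values.
* The pyramidal-slide reader is out of scope; inputs are plain RGB arrays
  (PNG/TIFF), with tiling assuming the full image fits in memory.
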