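# Methods

## Problem setting

Each case is a grayscale radiograph, a per-image table of expert fixations
(image-pixel coordinates, duration, onset), a set of elliptical expert ROIs
around localized findings, and a six-way multilabel target. The package
fuses the gaze signal with the image for multilabel abnormality
classification and scores post-hoc saliency explanations against the ROIs.
Coordinates are origin top-left, x rightward, y downward, 0-based, pixel
centers at integer + 0.5, everywhere.

## Fixation heatmap

The heatmap is a sum of isotropic Gaussian kernels at the fixation
coordinates, duration-weighted by default (fixation duration is the
attention-bearing quantity in reading studies; disable with
`duration_weighted=False`). Two quantities are deliberate modeling choices,
configurable and not measured from data:

* **Bandwidth** `sigma` — default `min(W, H) / 25`, a common saliency-map
  surrogate for roughly one degree of visual angle at typical viewing
  distance.
* **Normalization** — max-normalization to 1 (not mass normalization), so
  the heatmap channel occupies the same [0, 1] range as the image channel
  and neither modality dominates the early fusion numerically. A
  consequence worth knowing: absolute fixation mass is not preserved, so an
  image with one stray fixation still peaks at 1.

The RGB rendering uses a fixed piecewise-linear blue-to-red lookup table
whose mean channel intensity increases strictly with density, so density
rank order survives both colorization and any later grayscale conversion.
An empty gaze table produces an all-zero map (rendered at the low end).
Fixations beyond a 3-sigma margin outside the image warn but still
contribute their kernel tail.

`preprocess` applies the deterministic geometry (resize short side to
8/7 of the target, center-crop) in eval mode and adds seeded slight Gaussian
blur plus multiplicative brightness/contrast jitter (factors in
[0.8, 1.2]) in train mode. Heatmaps are rendered at native image size and
sent through the same geometric path as the image, which keeps the two
channels registered.

## Architecture

Early fusion: `(1 image + 3 heatmap-RGB) = 4` channels. The spatial
attention gate is two 1×1 convolutions (default hidden width 8) with ReLU
between, sigmoid scores, and optional dropout (default rate 0.1) on the
scores in train mode; the single-channel score map broadcasts over all
input channels (`gate_per_channel=True` switches to per-channel scores).
The gate multiplies the stacked input before the backbone, so attended
features stay elementwise bounded by the input.

The backbone is pluggable: named presets `tiny` (three 3×3 stride-2 blocks,
widths 16/32/32, feature dimension 32) and `tiny2` (two blocks, dimension
16), or any explicit `(width, stride)` list. A fixed `Shift(-0.5)` layer
centers the [0, 1] input first — without it, the all-positive input made
from-scratch training fragile (occasional full collapse to the base-rate
plateau). Global average pooling and a linear head give one logit per
class; sigmoid probabilities are thresholded at 0.5 by default.

`shared_backbone=False` builds the no-parameter-sharing baseline: separate
image and heatmap branches whose pooled features are concatenated before
the head (no gate). `build_image_only_model()` gives the 1-channel ablation
baseline. All layers, backpropagation, Adam, and the gradient capture used
for saliency are implemented on numpy arrays in `gazefusion.nn`; there is
no deep-learning-framework dependency, which also bounds the practical
model size to small CNNs (no pretrained ResNet variants).

## Training protocol

`TrainConfig` defaults follow a standard fine-tuning recipe: Adam,
learning rate 5e-5, weight decay 1e-3, batch size 32, 20 epochs, 80/10/10
per-image split, seed 42. Training tiny backbones from scratch needs a
different operating point — with six sigmoid outputs the per-class data
gradients are small and a 1e-3 decay term dominates them, pinning the loss
at the base-rate plateau — so the scaled phantom protocol
(`gazefusion.experiments`) uses lr 2e-3, weight decay 1e-4, 30 epochs.
Loss is unweighted mean binary cross-entropy in the numerically stable
log-sum-exp form. Early stopping (validation loss strictly rising for
`patience` consecutive epochs, default 3) is available but off by default.
Everything is seeded: initialization, shuffling, dropout; identical config
and seed reproduce loss curves exactly. The split is per-image; on real
multi-view data a per-patient split would be required to avoid leakage.

## Phantom generator

The generator emulates the statistical structure the method assumes, not
chest anatomy:

* **Background** — smooth random plane gradient around 0.45 plus i.i.d.
  Gaussian pixel noise (std 0.05).
* **Lesions** — additive blobs under a Gaussian envelope; the stored ellipse
  ROI is the envelope's 2-sigma contour, so ROI masks are exact by
  construction. Each class has a characteristic local appearance
  (bright/dark polarity × solid/ring/striped texture); classes must be
  locally distinguishable because a global-average-pooled CNN cannot
  discriminate blob extent. Default contrast 0.25 (5× the pixel-noise std),
  radius 6–12 px at the 64 px default size.
* **Clutter** — Poisson-distributed distractor blobs (rate 1.0) drawn from
  the same appearance family but unlabeled and never fixated. They are what
  makes gaze informative: the image alone cannot tell a lesion from a
  distractor of the same appearance, the fixation channel can.
* **Gaze** — a fraction `on_lesion_fraction` (default 0.9) of fixations
  targets a uniformly chosen lesion center with isotropic Gaussian scatter
  (std 2 px); the rest are uniform over the image. Durations are log-normal
  with median 250 ms — a plausible reading distribution, chosen as a
  placeholder rather than fitted to data. Saccade kinematics and tracker
  noise beyond positional scatter are not modeled.

What passing phantom tests does **not** show: anatomic realism, reader
variability, per-patient correlation structure, or the class imbalance and
label noise of clinical accessions. The phantom establishes that the
pipeline's machinery is correct and that the fusion mechanism can exploit
a gaze signal with the assumed structure — directional, not quantitative,
evidence about real data.

## Noise robustness

Striped-line corruption partitions heatmap rows (or columns) into bands of
the stripe thickness and overwrites a seeded random selection of
`round(level × n_bands)` bands, so the affected fraction matches the level
to one stripe quantum. Default fill erases evidence (zeros); `"shuffle"`
permutes values inside affected stripes instead, preserving intensity
statistics. Noise touches only heatmap channels, only at test time; the
image channel is bit-identical before and after. The sweep always includes
level 0 as the clean reference and reports macro one-vs-rest AUC.

## Grad-CAM and scoring

Gradients are taken from the pre-sigmoid logit of the target class; the
hooked layer defaults to the last backbone activation (the deepest
convolutional stage). Channel weights are spatially averaged gradients;
the raw map is the ReLU of the weighted activation sum. Display
post-processing: min-max normalization (an all-constant map — including
all-zero — normalizes to all-zero with a warning, avoiding spurious
full-saturation overlays), optional vertical flip (off by default; the
phantom's coordinates need no orientation fix), bilinear upscale to input
size, colormap rendering. Maps can be computed per ground-truth or per
predicted class; the evaluation CLI uses ground-truth classes.

For scoring, the normalized display is binarized at a cutoff (default 0.5,
always reported with the result) and compared with the union of the
class's ellipse masks by IoU; the mIoU is the unweighted mean over classes.
Two masks that are both empty score 1.0 (a correctly absent finding) but
such classes are excluded from aggregates by default.

### Localization protocol

Grad-CAM localizes class-discriminative evidence. With a single lesion
class and featureless negatives, a classifier is free to encode the label
by *suppressing* background evidence — it classifies perfectly while its
positive-evidence map is uninformative (we observed exactly this: hit rate
0 at every hook depth despite separable logits). The localization protocol
therefore poses a discrimination task: two lesion appearances (target:
solid bright blob; contrast: dark ring), radius 8–14 px, no clutter,
prevalence 0.5 each, trained to saturation. Under that protocol the
saliency argmax lands inside the planted ROI for ~85–100% of positive test
cases and the thresholded-CAM mIoU clearly exceeds an untrained model's.

## Problem sizes

The scaled experiments use 600 cases at 64×64 with the `tiny` backbone for
the modality ablation and noise sweep (five seeded replicates), 300 cases
for localization, and 8 cases for the memorization check — sizes chosen so
the full suite and the acceptance script each run in minutes on one CPU
while keeping the directional effects stable across seeds.

## Known limitations

* Backbones are small from-scratch CNNs; no pretrained weights, so absolute
  metric levels are far below what a fine-tuned ResNet reaches on real data.
* Max-normalized heatmaps discard absolute fixation mass.
* The both-empty IoU convention (1.0, excluded by default) and the CAM
  binarization cutoff materially affect mIoU values; both are reported
  alongside scores.
* The phantom's gaze model is positional only; drift, calibration error and
  saccade dynamics are out of scope.
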