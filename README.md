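# gazefusion

Gaze-guided multimodal fusion for chest-radiograph abnormality
classification, with built-in explanation scoring.

Radiologists' eye movements concentrate on diagnostically relevant regions.
This package turns that signal into a model input: per-image fixation tables
are rendered into an expert fixation heatmap, fused with the radiograph at
the input level, and classified by an attention-gated CNN. The package is
aimed at researchers studying gaze-guided learning and saliency-based
explanation — it ships a synthetic phantom generator that emulates the full
data bundle (radiograph, fixations, ellipse ROIs, multilabel targets), so
every stage runs end to end with no external dataset.

## Model

Given a grayscale radiograph `I_CXR ∈ [0,1]^{W×H}` and fixation records
`(x_f, y_f, d_f)`, the fixation heatmap is the max-normalized,
duration-weighted Gaussian kernel sum

    H(p) ∝ Σ_f d_f · exp(−‖p − p_f‖² / 2σ²),

rendered through a fixed blue-to-red lookup table. The fusion input stacks
the image with the heatmap RGB along channels,

    I_multi = Concat(I_CXR, rgb(H)) ∈ [0,1]^{4×W×H},

and passes through an attention gate built from two 1×1 convolutions,

    A = σ(W₂ ∗ ReLU(W₁ ∗ I_multi + b₁) + b₂),   F = I_multi ⊙ A,

a shared convolutional backbone with global average pooling, and a fully
connected head emitting one independent sigmoid logit per abnormality class
(multilabel; threshold 0.5 by default). Training is seeded Adam on mean
binary cross-entropy.

Explanations use gradient-weighted class activation mapping: for class `c`
and hooked layer activations `A^k`, channel weights are the spatially
averaged logit gradients `α_k = (1/Z) Σ_ij ∂y_c/∂A^k_ij` and the map is
`ReLU(Σ_k α_k A^k)`, normalized, upscaled, and scored against expert
ellipse ROIs by per-class intersection-over-union and its mean (mIoU).
Robustness to tracker misalignment is probed by overwriting random stripes
of the heatmap channels at test time and tracking macro AUC.

Because no deep-learning framework is assumed, the convolutional layers,
attention gate, backpropagation, Adam and the Grad-CAM hooks are implemented
directly on numpy arrays (`gazefusion.nn`); backbones are small pluggable
CNNs (`"tiny"`, `"tiny2"`, or explicit block lists).

## Worked example

```python
import numpy as np
from gazefusion import (PhantomConfig, generate_phantom_dataset, split_dataset,
                        stack_dataset, GazeFusionClassifier, classification_metrics,
                        capture_activations, gradcam, postprocess_cam,
                        roi_masks_by_class, binarize_cam, compute_miou)

cfg = PhantomConfig(n_samples=300, image_size=64, seed=0)
samples = generate_phantom_dataset(cfg)
train_s, val_s, test_s = split_dataset(samples, (0.8, 0.1, 0.1), seed=0)
X_tr, y_tr = stack_dataset(train_s)          # (N, 4, 64, 64) fusion stacks
X_te, y_te = stack_dataset(test_s)

clf = GazeFusionClassifier(epochs=30, learning_rate=2e-3, weight_decay=1e-4,
                           random_state=0).fit(X_tr, y_tr)
cm = classification_metrics(clf.predict_proba(X_te), y_te)
print("macro:", {k: round(v, 3) for k, v in cm.macro.items()})

i = next(j for j, s in enumerate(test_s) if s.labels.sum() > 0)
c = int(np.flatnonzero(test_s[i].labels)[0])
cap = capture_activations(clf, X_te[i], target_class=c)
display = postprocess_cam(gradcam(cap), 64, 64)
roi = roi_masks_by_class(test_s[i].rois, 64, 64, 6)[c]
report = compute_miou(binarize_cam(display, 0.5)[None], roi[None])
print(f"sample {i}, class {c}: CAM-vs-ROI IoU = {report.miou:.3f}")
```

Output:

```
macro: {'accuracy': 0.733, 'precision': 0.29, 'recall': 0.215, 'f1': 0.231, 'auc': 0.767}
sample 0, class 0: CAM-vs-ROI IoU = 0.324
```

The macro row averages per-class test metrics over the six phantom classes
(multilabel, prevalence 0.3 each): the fused model ranks positives well
(AUC 0.77) at this small training size, and the Grad-CAM map for the first
positive test case overlaps its planted lesion ellipse with IoU 0.32 at the
0.5 binarization cutoff. A command-line interface mirrors the library
(`gazefusion simulate | heatmap | train | evaluate | noise-test |
explain-eval`); see `gazefusion --help`.

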