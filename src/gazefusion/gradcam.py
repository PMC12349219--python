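"""Gradient-weighted class activation mapping (Grad-CAM) with post-processing.

For a target class c and a hooked convolutional layer with activations
A^k at spatial positions (i, j), the channel weights are the spatially
averaged gradients of the pre-sigmoid class logit,

    alpha_k = (1/Z) sum_ij  d y_c / d A^k_ij,

and the raw map is ReLU(sum_k alpha_k A^k) at the hooked layer's resolution.
The backward pass is taken from the logit, not the probability. The display
rendering min-max normalizes the raw map (an all-constant map becomes
all-zero, with a warning), optionally flips vertically (a dataset-specific
orientation fix, off by default), upscales bilinearly to the input size and
colorizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.utils.validation import check_is_fitted
from skimage.transform import resize as _sk_resize

from .heatmap import colorize
from .nn import Sequential

__all__ = [
    "ActivationCapture",
    "GradCAMMap",
    "capture_activations",
    "gradcam",
    "postprocess_cam",
    "explain_batch",
]


@dataclass
class ActivationCapture:
    """Hooked-layer activations and logit gradients for one input and class."""

    activations: np.ndarray  # (K, h, w)
    gradients: np.ndarray    # (K, h, w) = d y_c / d A^k
    target_class: int
    layer: str

    @property
    def Z(self) -> int:
        return int(self.activations.shape[1] * self.activations.shape[2])


@dataclass
class GradCAMMap:
    raw: np.ndarray                    # (h, w), nonnegative
    weights: np.ndarray                # (K,) channel weights alpha_k
    target_class: int
    layer: str
    display: np.ndarray | None = field(default=None)  # set by postprocess_cam


def _resolve_network(model) -> Sequential:
    check_is_fitted(model, "network_")
    net = model.network_
    if not isinstance(net, Sequential):
        raise ValueError("class-activation mapping requires a shared-backbone model")
    return net


def capture_activations(model, x: np.ndarray, target_layer: str | None = None,
                        target_class: int = 0) -> ActivationCapture:
    """One eval-mode forward pass and one backward pass from logit y_c.

    ``x`` is a single input, shape (C, H, W). Model weights are not mutated.
    ``target_layer`` defaults to the final backbone activation (the deepest
    convolutional stage before pooling).
    """
    net = _resolve_network(model)
    layer = target_layer or model.cam_layer_
    if layer not in net.layer_names:
        raise ValueError(f"no layer named {layer!r}; available: {net.layer_names}")
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 3:
        x = x[None]
    if x.shape[0] != 1:
        raise ValueError(f"capture_activations takes a single input, got batch {x.shape}")

    logits = net.forward(x, train=False)
    if not 0 <= target_class < logits.shape[1]:
        raise ValueError(f"target_class {target_class} out of range [0, {logits.shape[1]})")
    acts = net.activations[layer]
    if acts.ndim != 4:
        raise ValueError(f"layer {layer!r} is not spatial (shape {acts.shape}); "
                         "hook a convolutional layer")
    seed = np.zeros_like(logits)
    seed[0, target_class] = 1.0
    _, grad = net.backward(seed, capture=layer)
    return ActivationCapture(activations=acts[0].copy(), gradients=grad[0],
                             target_class=target_class, layer=layer)


def gradcam(capture: ActivationCapture) -> GradCAMMap:
    """Channel-weight pooling and ReLU-rectified weighted sum."""
    if capture.Z == 0:
        raise ValueError("capture has zero spatial locations")
    alpha = capture.gradients.mean(axis=(1, 2))
    raw = np.einsum("k,khw->hw", alpha, capture.activations)
    raw = np.maximum(raw, 0.0)
    return GradCAMMap(raw=raw, weights=alpha, target_class=capture.target_class,
                      layer=capture.layer)


def postprocess_cam(cam: GradCAMMap, out_width: int, out_height: int,
                    flip_vertical: bool = False) -> np.ndarray:
    """Normalize, optionally flip, and bilinearly upscale the raw map.

    Min-max normalization maps a constant raw map (including all-zero) to
    all-zero with a warning — a flat map carries no localization evidence.
    The normalized display is stored on ``cam.display`` and returned.
    """
    if out_width <= 0 or out_height <= 0:
        raise ValueError(f"output dims must be positive, got {out_width}x{out_height}")
    raw = np.asarray(cam.raw, dtype=np.float64)
    if raw.size == 0:
        raise ValueError("raw map is empty")
    lo, hi = raw.min(), raw.max()
    if hi - lo <= 0:
        if hi > 0:
            warnings.warn("constant nonzero raw map normalized to all-zero", stacklevel=2)
        norm = np.zeros_like(raw)
    else:
        norm = (raw - lo) / (hi - lo)
    if flip_vertical:
        norm = norm[::-1]
    display = _sk_resize(norm, (out_height, out_width), order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True)
    display = np.clip(display, 0.0, 1.0)
    cam.display = display
    return display


def overlay(image: np.ndarray, display: np.ndarray, alpha: float = 0.4) -> np.ndarray:
    """Blend a colorized CAM display onto a grayscale image, (H, W, 3) output."""
    img = np.clip(np.asarray(image, dtype=np.float64), 0, 1)
    if img.shape != display.shape:
        raise ValueError(f"image {img.shape} and display {display.shape} shapes differ")
    return (1 - alpha) * img[..., None] + alpha * colorize(display)


def explain_batch(model, X: np.ndarray, target_layer: str | None = None,
                  classes=None, alpha: float = 0.4,
                  flip_vertical: bool = False) -> list[dict]:
    """Grad-CAM maps and overlays for every (sample, class) pair.

    Returns a list of dicts with keys ``sample``, ``class``, ``cam``
    (GradCAMMap with ``display`` set at input resolution) and ``overlay``.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 4:
        raise ValueError(f"expected (N, C, H, W) batch, got {X.shape}")
    if classes is None:
        classes = range(model.n_classes_)
    out = []
    h, w = X.shape[2], X.shape[3]
    for i in range(len(X)):
        for c in classes:
            cap = capture_activations(model, X[i], target_layer=target_layer,
                                      target_class=int(c))
            cam = gradcam(cap)
            display = postprocess_cam(cam, w, h, flip_vertical=flip_vertical)
            out.append({"sample": i, "class": int(c), "cam": cam,
                        "overlay": overlay(X[i, 0], display, alpha=alpha)})
    return out
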