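"""Fixation-heatmap construction and image preprocessing.

A fixation heatmap is the max-normalized sum of isotropic Gaussian kernels
centered at the fixation coordinates, optionally weighted by fixation
duration (on by default: duration is the attention-bearing quantity in
reading studies). The map is rendered at native image resolution and then
sent through the same geometric preprocessing as the radiograph so the two
stay spatially registered.

The kernel bandwidth is not a measured quantity; the default
``sigma = min(W, H) / 25`` is a common saliency-map surrogate for about one
degree of visual angle and is configurable everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "GazeRecord",
    "FixationHeatmap",
    "render_fixation_heatmap",
    "colorize",
    "preprocess",
    "default_sigma",
    "read_gaze_csv",
]


@dataclass(frozen=True)
class GazeRecord:
    """One fixation event in image pixel coordinates."""

    x: float
    y: float
    duration: float = 250.0  # milliseconds
    t_start: float = 0.0

    def __post_init__(self):
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"fixation coordinates must be finite, got ({self.x}, {self.y})")
        if self.duration < 0:
            raise ValueError(f"fixation duration must be >= 0, got {self.duration}")


@dataclass
class FixationHeatmap:
    """Nonnegative fixation density (max 1 unless empty) plus its RGB rendering."""

    density: np.ndarray
    rgb: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.density.shape


def default_sigma(width: int, height: int) -> float:
    return min(width, height) / 25.0


# Blue-to-red lookup table with strictly increasing mean channel intensity,
# so rank order of densities survives both colorization and grayscale
# conversion. Node colors: deep blue -> azure -> teal -> amber -> warm red.
_LUT_NODES_T = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
_LUT_NODES_RGB = np.array([
    [0.00, 0.00, 0.60],
    [0.00, 0.45, 0.95],
    [0.30, 0.80, 0.60],
    [0.85, 0.70, 0.20],
    [1.00, 0.45, 0.35],
])
_LUT = np.stack(
    [np.interp(np.linspace(0, 1, 256), _LUT_NODES_T, _LUT_NODES_RGB[:, c]) for c in range(3)],
    axis=1,
)


def colorize(density: np.ndarray) -> np.ndarray:
    """Map a [0,1] density grid to an (H, W, 3) blue-to-red rendering.

    Equal densities map to equal colors; values outside [0,1] are clipped
    with a warning.
    """
    d = np.asarray(density, dtype=np.float64)
    if d.min() < 0 or d.max() > 1:
        warnings.warn("density values outside [0, 1] clipped before colorization",
                      stacklevel=2)
        d = np.clip(d, 0.0, 1.0)
    idx = np.round(d * 255).astype(np.intp)
    return _LUT[idx]


def render_fixation_heatmap(
    gaze: list[GazeRecord],
    width: int,
    height: int,
    sigma: float | None = None,
    duration_weighted: bool = True,
) -> FixationHeatmap:
    """Build the expert fixation heatmap from fixation coordinates.

    The density is ``sum_f w_f * exp(-((x-x_f)^2+(y-y_f)^2) / (2 sigma^2))``
    evaluated at pixel centers, max-normalized to 1; ``w_f`` is the fixation
    duration when ``duration_weighted`` (else 1). An empty gaze list yields
    an all-zero map. Fixations far outside the image (beyond a 3-sigma
    margin) raise a warning but still contribute through the kernel tail.
    """
    if width < 1 or height < 1:
        raise ValueError(f"width and height must be >= 1, got {width}x{height}")
    if sigma is None:
        sigma = default_sigma(width, height)
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")

    density = np.zeros((height, width), dtype=np.float64)
    xs = np.arange(width) + 0.5
    ys = np.arange(height) + 0.5
    for g in gaze:
        if (g.x < -3 * sigma or g.x > width + 3 * sigma
                or g.y < -3 * sigma or g.y > height + 3 * sigma):
            warnings.warn(
                f"fixation at ({g.x:.1f}, {g.y:.1f}) lies beyond the 3-sigma margin "
                f"of a {width}x{height} image", stacklevel=2)
        w = g.duration if duration_weighted else 1.0
        kx = np.exp(-((xs - g.x) ** 2) / (2 * sigma**2))
        ky = np.exp(-((ys - g.y) ** 2) / (2 * sigma**2))
        density += w * np.outer(ky, kx)

    peak = density.max()
    if peak > 0:
        density /= peak
    return FixationHeatmap(density=density, rgb=colorize(density))


def _resize(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    return _sk_resize(image, shape, order=1, mode="edge", anti_aliasing=True,
                      preserve_range=True)


def preprocess(
    image: np.ndarray,
    train_mode: bool = False,
    aug_seed: int = 0,
    out_size: int = 224,
    jitter: float = 0.2,
    blur_sigma_range: tuple[float, float] = (0.1, 1.0),
) -> np.ndarray:
    """Resize/crop (always) and blur + brightness/contrast jitter (train only).

    Eval mode is deterministic: resize the short side to ``out_size * 8/7``
    then center-crop ``out_size``. Train mode additionally applies a seeded
    slight Gaussian blur and multiplicative brightness/contrast jitter with
    factors drawn from ``[1 - jitter, 1 + jitter]``; output is clipped to
    the input's [0, 1] range.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("cannot preprocess an empty image")
    h, w = img.shape
    scale = (out_size * 8 / 7) / min(h, w)
    rh, rw = max(out_size, int(round(h * scale))), max(out_size, int(round(w * scale)))
    img = _resize(img, (rh, rw))
    top, left = (rh - out_size) // 2, (rw - out_size) // 2
    img = img[top : top + out_size, left : left + out_size]

    if train_mode:
        rng = np.random.default_rng(aug_seed)
        sig = rng.uniform(*blur_sigma_range)
        img = ndimage.gaussian_filter(img, sig, mode="nearest")
        brightness = rng.uniform(1 - jitter, 1 + jitter)
        contrast = rng.uniform(1 - jitter, 1 + jitter)
        mean = img.mean()
        img = (img - mean) * contrast + mean
        img = np.clip(img * brightness, 0.0, 1.0)
    return img


def read_gaze_csv(path) -> list[GazeRecord]:
    """Read a REFLACX-style fixation table (x_px, y_px, duration_ms, t_start_ms)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"x_px", "y_px"}
    if not required.issubset(df.columns):
        raise ValueError(f"gaze CSV must contain columns {sorted(required)}, got {list(df.columns)}")
    return [
        GazeRecord(
            x=float(r.x_px), y=float(r.y_px),
            duration=float(getattr(r, "duration_ms", 250.0)),
            t_start=float(getattr(r, "t_start_ms", 0.0)),
        )
        for r in df.itertuples()
    ]
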