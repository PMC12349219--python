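"""Synthetic chest-phantom generator.

Produces seeded phantom radiographs with planted elliptical lesions, six-way
multilabel targets, expert-like fixation tables concentrated on the lesions,
and exact ellipse ROIs — the full input bundle the fusion pipeline consumes,
so every downstream stage is testable without any external accession.

Image model
-----------
Background = smooth plane gradient + low-frequency "anatomic" clutter blobs +
i.i.d. Gaussian pixel noise (std 0.05). Lesions are additive blobs under a
Gaussian envelope; each abnormality class has a characteristic local
appearance (bright/dark polarity x solid/ring/striped texture) so classes
are separable from pixels alone, while the clutter blobs mimic lesion
appearance and are *not* fixated — gaze therefore carries genuine
disambiguating information, as it does for radiologists.

The ellipse ROI stored for a lesion is the blob's 2-sigma contour, so ROI
masks are exact by construction.

Coordinates: origin top-left, x rightward, y downward, 0-based, pixel centers
at integer + 0.5. This convention is used everywhere in the package.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .heatmap import GazeRecord

__all__ = [
    "PhantomConfig",
    "EllipseROI",
    "PhantomSample",
    "generate_phantom_dataset",
    "ellipse_to_mask",
    "roi_masks_by_class",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class EllipseROI:
    """Elliptical region of interest around a localized finding.

    ``a`` is the semi-axis along the rotated x'-axis, ``b`` along y';
    ``theta_deg`` rotates the ellipse counterclockwise in the x-right /
    y-down pixel frame.
    """

    cx: float
    cy: float
    a: float
    b: float
    theta_deg: float = 0.0
    class_idx: int = 0


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters for the phantom dataset."""

    n_samples: int = 100
    image_size: int = 64
    n_classes: int = 6
    class_prevalence: float | tuple[float, ...] = 0.3
    lesion_intensity: float = 0.25
    lesion_radius_range: tuple[float, float] = (6.0, 12.0)
    fixation_count_range: tuple[int, int] = (8, 20)
    on_lesion_fraction: float = 0.9
    fixation_scatter: float = 2.0
    distractor_blob_rate: float = 1.0
    noise_std: float = 0.05
    seed: int = 0

    def prevalence_vector(self) -> np.ndarray:
        p = np.asarray(self.class_prevalence, dtype=float)
        if p.ndim == 0:
            p = np.full(self.n_classes, float(p))
        return p

    def validate(self) -> None:
        if self.n_samples < 0:
            raise ValueError(f"n_samples must be >= 0, got {self.n_samples}")
        if self.image_size < 16:
            raise ValueError(f"image_size must be >= 16, got {self.image_size}")
        if self.n_classes < 1:
            raise ValueError(f"n_classes must be >= 1, got {self.n_classes}")
        p = self.prevalence_vector()
        if p.shape != (self.n_classes,):
            raise ValueError(
                f"class_prevalence must be scalar or length {self.n_classes}"
            )
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("class_prevalence entries must lie in [0, 1]")
        if not 0.0 <= self.lesion_intensity <= 1.0:
            raise ValueError(f"lesion_intensity must be in [0, 1], got {self.lesion_intensity}")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi):
            raise ValueError(f"lesion_radius_range must satisfy 0 < lo <= hi, got {self.lesion_radius_range}")
        if hi >= self.image_size / 2:
            raise ValueError(
                f"lesion_radius_range upper bound {hi} must be < image_size/2 = {self.image_size / 2}"
            )
        flo, fhi = self.fixation_count_range
        if not (0 <= flo <= fhi):
            raise ValueError(f"fixation_count_range invalid: {self.fixation_count_range}")
        if not 0.0 <= self.on_lesion_fraction <= 1.0:
            raise ValueError(f"on_lesion_fraction must be in [0, 1], got {self.on_lesion_fraction}")
        if self.fixation_scatter < 0:
            raise ValueError(f"fixation_scatter must be >= 0, got {self.fixation_scatter}")
        if self.distractor_blob_rate < 0:
            raise ValueError(f"distractor_blob_rate must be >= 0, got {self.distractor_blob_rate}")
        if self.noise_std < 0:
            raise ValueError(f"noise_std must be >= 0, got {self.noise_std}")


@dataclass
class PhantomSample:
    """One phantom case: image in [0,1], binary labels, ROIs and gaze."""

    image: np.ndarray
    labels: np.ndarray
    rois: list[EllipseROI] = field(default_factory=list)
    gaze: list[GazeRecord] = field(default_factory=list)


def ellipse_to_mask(roi: EllipseROI, width: int, height: int) -> np.ndarray:
    """Rasterize a rotated ellipse: a pixel is set iff its center satisfies
    the rotated-ellipse inequality <= 1."""
    if roi.a <= 0 or roi.b <= 0:
        raise ValueError(f"ellipse semi-axes must be positive, got a={roi.a}, b={roi.b}")
    yy, xx = np.mgrid[0:height, 0:width]
    dx = (xx + 0.5) - roi.cx
    dy = (yy + 0.5) - roi.cy
    t = math.radians(roi.theta_deg)
    u = dx * math.cos(t) + dy * math.sin(t)
    v = -dx * math.sin(t) + dy * math.cos(t)
    return (u / roi.a) ** 2 + (v / roi.b) ** 2 <= 1.0


def roi_masks_by_class(rois: list[EllipseROI], width: int, height: int,
                       n_classes: int) -> np.ndarray:
    """Union of ROI masks per class, shape (n_classes, height, width)."""
    masks = np.zeros((n_classes, height, width), dtype=bool)
    for roi in rois:
        masks[roi.class_idx] |= ellipse_to_mask(roi, width, height)
    return masks


def _class_appearance(class_idx: int, cfg: PhantomConfig, rng: np.random.Generator):
    """Characteristic lesion appearance for a class: polarity x local texture.

    Classes 0..2 are bright (additive), 3..5 dark; textures cycle through
    solid blob, annular ring and striped blob, giving six locally
    distinguishable appearance signatures (loosely mirroring how findings
    like consolidation vs pleural lines differ in local pattern, not just
    extent). A single-class phantom uses a solid bright blob.
    """
    lo, hi = cfg.lesion_radius_range
    r = rng.uniform(lo, hi)
    if cfg.n_classes == 1:
        return r, 1.0, 0
    polarity = 1.0 if class_idx < (cfg.n_classes + 1) // 2 else -1.0
    texture = class_idx % 3
    return r, polarity, texture


def _add_blob(image: np.ndarray, roi: EllipseROI, amplitude: float,
              texture: int = 0) -> None:
    """Additive lesion whose 2-sigma envelope contour is `roi`.

    texture 0: Gaussian blob; 1: annular ring peaking at 0.65 of the ROI
    radius; 2: Gaussian blob modulated by 4 px stripes along the major axis.
    """
    h, w = image.shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx = (xx + 0.5) - roi.cx
    dy = (yy + 0.5) - roi.cy
    t = math.radians(roi.theta_deg)
    u = dx * math.cos(t) + dy * math.sin(t)
    v = -dx * math.sin(t) + dy * math.cos(t)
    rho2 = (u / roi.a) ** 2 + (v / roi.b) ** 2  # normalized elliptic radius^2
    if texture == 1:
        rho = np.sqrt(rho2)
        profile = np.exp(-0.5 * ((rho - 0.65) / 0.18) ** 2)
    else:
        profile = np.exp(-2.0 * rho2)  # 2-sigma at rho = 1
        if texture == 2:
            profile = profile * (0.55 + 0.45 * np.cos(2 * np.pi * u / 4.0))
    image += amplitude * profile


def _random_ellipse(cx: float, cy: float, r: float, rng: np.random.Generator,
                    class_idx: int) -> EllipseROI:
    ecc = rng.uniform(0.7, 1.0)
    return EllipseROI(cx=cx, cy=cy, a=r, b=r * ecc,
                      theta_deg=float(rng.uniform(0.0, 180.0)), class_idx=class_idx)


def _background(size: int, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size] / size
    gx, gy = rng.uniform(-0.15, 0.15, 2)
    return 0.45 + gx * (xx - 0.5) + gy * (yy - 0.5)


def generate_phantom_dataset(config: PhantomConfig) -> list[PhantomSample]:
    """Generate ``config.n_samples`` seeded phantom cases.

    Identical configs (including seed) give bitwise-identical datasets. A
    positive label always comes with exactly one planted lesion ROI of that
    class; a fraction ``on_lesion_fraction`` of fixations targets a lesion
    center (with isotropic Gaussian scatter), the rest are uniform
    distractor fixations.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    prevalence = config.prevalence_vector()
    samples: list[PhantomSample] = []

    for _ in range(config.n_samples):
        labels = (rng.random(config.n_classes) < prevalence).astype(np.int8)
        image = _background(size, rng)

        rois: list[EllipseROI] = []
        for k in np.flatnonzero(labels):
            r, polarity, texture = _class_appearance(int(k), config, rng)
            margin = r + 1.0
            cx = rng.uniform(margin, size - margin)
            cy = rng.uniform(margin, size - margin)
            roi = _random_ellipse(cx, cy, r, rng, int(k))
            _add_blob(image, roi, polarity * config.lesion_intensity, texture)
            rois.append(roi)

        # Clutter blobs: lesion-like appearance, unlabeled and never fixated.
        n_clutter = rng.poisson(config.distractor_blob_rate)
        for _ in range(n_clutter):
            fake_class = int(rng.integers(config.n_classes))
            r, polarity, texture = _class_appearance(fake_class, config, rng)
            margin = r + 1.0
            cx = rng.uniform(margin, size - margin)
            cy = rng.uniform(margin, size - margin)
            fake = _random_ellipse(cx, cy, r, rng, fake_class)
            _add_blob(image, fake, polarity * config.lesion_intensity, texture)

        if config.noise_std > 0:
            image += rng.normal(0.0, config.noise_std, image.shape)
        image = np.clip(image, 0.0, 1.0)

        gaze: list[GazeRecord] = []
        flo, fhi = config.fixation_count_range
        n_fix = int(rng.integers(flo, fhi + 1))
        t = 0.0
        for _ in range(n_fix):
            on_lesion = rois and (rng.random() < config.on_lesion_fraction)
            if on_lesion:
                roi = rois[int(rng.integers(len(rois)))]
                x = roi.cx + rng.normal(0.0, config.fixation_scatter)
                y = roi.cy + rng.normal(0.0, config.fixation_scatter)
            else:
                x = rng.uniform(0.0, size)
                y = rng.uniform(0.0, size)
            x = float(np.clip(x, 0.0, size - 1e-6))
            y = float(np.clip(y, 0.0, size - 1e-6))
            # Durations: log-normal with 250 ms median — a plausible reading
            # distribution; the duration law is a modeling choice, not data-driven.
            duration = float(250.0 * np.exp(rng.normal(0.0, 0.5)))
            gaze.append(GazeRecord(x=x, y=y, duration=duration, t_start=t))
            t += duration + float(rng.uniform(20.0, 80.0))  # saccade gap

        samples.append(PhantomSample(image=image, labels=labels, rois=rois, gaze=gaze))

    return samples


# ---------------------------------------------------------------------------
# Plain-text dataset layout: PNG images + per-image gaze CSV + ellipse CSV +
# label CSV + manifest CSV, mirroring a REFLACX-style directory.
# ---------------------------------------------------------------------------

def write_dataset(samples: list[PhantomSample], outdir: str | Path) -> Path:
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "gaze").mkdir(parents=True, exist_ok=True)

    roi_rows, label_rows, manifest_rows = [], [], []
    for i, s in enumerate(samples):
        image_id = f"img_{i:05d}"
        img_path = outdir / "images" / f"{image_id}.png"
        Image.fromarray((np.clip(s.image, 0, 1) * 255).round().astype(np.uint8)).save(img_path)

        gaze_path = outdir / "gaze" / f"{image_id}_gaze.csv"
        pd.DataFrame(
            [{"x_px": g.x, "y_px": g.y, "duration_ms": g.duration, "t_start_ms": g.t_start}
             for g in s.gaze]
        ).to_csv(gaze_path, index=False)

        for roi in s.rois:
            roi_rows.append({"image_id": image_id, "class": roi.class_idx,
                             "cx": roi.cx, "cy": roi.cy, "a": roi.a, "b": roi.b,
                             "theta_deg": roi.theta_deg})
        label_rows.append({"image_id": image_id,
                           **{f"class_{k}": int(v) for k, v in enumerate(s.labels)}})
        manifest_rows.append({"image_id": image_id,
                              "image": str(img_path.relative_to(outdir)),
                              "gaze": str(gaze_path.relative_to(outdir))})

    pd.DataFrame(roi_rows, columns=["image_id", "class", "cx", "cy", "a", "b", "theta_deg"]).to_csv(
        outdir / "rois.csv", index=False)
    pd.DataFrame(label_rows).to_csv(outdir / "labels.csv", index=False)
    pd.DataFrame(manifest_rows).to_csv(outdir / "manifest.csv", index=False)
    return outdir / "manifest.csv"


def read_dataset(root: str | Path) -> list[PhantomSample]:
    """Load a dataset written by :func:`write_dataset` (8-bit image quantization)."""
    root = Path(root)
    manifest = pd.read_csv(root / "manifest.csv")
    rois = pd.read_csv(root / "rois.csv")
    labels = pd.read_csv(root / "labels.csv").set_index("image_id")
    class_cols = [c for c in labels.columns if c.startswith("class_")]

    samples = []
    for _, row in manifest.iterrows():
        image = np.asarray(Image.open(root / row["image"]), dtype=np.float64) / 255.0
        gz = pd.read_csv(root / row["gaze"])
        gaze = [GazeRecord(x=r.x_px, y=r.y_px, duration=r.duration_ms, t_start=r.t_start_ms)
                for r in gz.itertuples()]
        sub = rois[rois["image_id"] == row["image_id"]]
        sample_rois = [EllipseROI(cx=r.cx, cy=r.cy, a=r.a, b=r.b, theta_deg=r.theta_deg,
                                  class_idx=int(r[1])) for r in sub.itertuples(index=False)]
        y = labels.loc[row["image_id"], class_cols].to_numpy(dtype=np.int8)
        samples.append(PhantomSample(image=image, labels=y, rois=sample_rois, gaze=gaze))
    return samples


def config_from_dict(d: dict) -> PhantomConfig:
    """Build a config from a JSON-style dict, coercing list fields to tuples."""
    kwargs = dict(d)
    for key in ("lesion_radius_range", "fixation_count_range", "class_prevalence"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    valid = {f.name for f in dataclasses.fields(PhantomConfig)}
    unknown = set(kwargs) - valid
    if unknown:
        raise ValueError(f"unknown PhantomConfig fields: {sorted(unknown)}")
    return PhantomConfig(**kwargs)
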