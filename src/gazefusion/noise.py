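"""Striped-line noise injection for fixation heatmaps and the robustness sweep.

Tracker misalignment is emulated by overwriting a seeded random subset of
full-width horizontal (or full-height vertical) stripes of a given thickness
in the heatmap. The image channel is never touched. The stripe bands
partition the rows, so the affected-pixel fraction matches the requested
level to within one stripe quantum. The default fill erases fixation
evidence (zeros); a "shuffle" fill instead permutes the pixel values inside
each affected stripe, preserving intensity statistics while destroying
spatial structure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .heatmap import FixationHeatmap, colorize
from .metrics import macro_auc

__all__ = ["NoiseSpec", "inject_striped_noise", "corrupt_stack", "run_noise_sweep"]


@dataclass(frozen=True)
class NoiseSpec:
    level: float = 0.1
    stripe_thickness: int = 2
    orientation: str = "horizontal"
    fill: str = "zero"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.level <= 1.0:
            raise ValueError(f"noise level must be in [0, 1], got {self.level}")
        if self.stripe_thickness < 1:
            raise ValueError(f"stripe_thickness must be >= 1, got {self.stripe_thickness}")
        if self.orientation not in ("horizontal", "vertical"):
            raise ValueError(f"orientation must be horizontal|vertical, got {self.orientation!r}")
        if self.fill not in ("zero", "shuffle"):
            raise ValueError(f"fill must be zero|shuffle, got {self.fill!r}")


def _stripe_row_mask(n_rows: int, spec: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    """Boolean row mask: rows are partitioned into bands of the stripe
    thickness and round(level * n_bands) bands are selected."""
    t = spec.stripe_thickness
    if t > n_rows:
        raise ValueError(f"stripe_thickness {t} exceeds image extent {n_rows}")
    n_bands = int(np.ceil(n_rows / t))
    k = int(round(spec.level * n_bands))
    chosen = rng.choice(n_bands, size=k, replace=False)
    mask = np.zeros(n_rows, dtype=bool)
    for b in chosen:
        mask[b * t : (b + 1) * t] = True
    return mask


def _apply_rows(grid: np.ndarray, mask: np.ndarray, spec: NoiseSpec,
                rng: np.random.Generator) -> np.ndarray:
    """Overwrite masked rows of a 2-D grid per the fill policy."""
    out = grid.copy()
    if spec.fill == "zero":
        out[mask] = 0.0
    else:  # shuffle values within the affected region
        vals = out[mask].ravel()
        out[mask] = rng.permutation(vals).reshape(out[mask].shape)
    return out


def inject_striped_noise(heatmap: FixationHeatmap, spec: NoiseSpec) -> FixationHeatmap:
    """Corrupt a fixation heatmap with striped-line noise; level 0 is identity.

    Returns a new heatmap whose RGB rendering is recomputed from the
    corrupted density, so density and rgb stay consistent.
    """
    spec.validate()
    density = np.asarray(heatmap.density)
    h, w = density.shape
    if spec.level == 0.0:
        return FixationHeatmap(density=density.copy(), rgb=heatmap.rgb.copy())
    rng = np.random.default_rng(spec.seed)
    if spec.orientation == "horizontal":
        mask = _stripe_row_mask(h, spec, rng)
        new_density = _apply_rows(density, mask, spec, rng)
    else:
        mask = _stripe_row_mask(w, spec, rng)
        new_density = _apply_rows(density.T, mask, spec, rng).T
    return FixationHeatmap(density=new_density, rgb=colorize(np.clip(new_density, 0, 1)))


def corrupt_stack(X: np.ndarray, spec: NoiseSpec, image_channels: int = 1) -> np.ndarray:
    """Apply striped noise to the heatmap channels of a batch of fusion stacks.

    Channels ``[0, image_channels)`` (the radiograph) are left bit-identical;
    1-channel image-only batches pass through untouched. Each sample gets an
    independent stripe pattern derived from ``spec.seed``.
    """
    spec.validate()
    X = np.asarray(X)
    if X.ndim != 4:
        raise ValueError(f"expected (N, C, H, W) batch, got shape {X.shape}")
    if X.shape[1] <= image_channels or spec.level == 0.0:
        return X.copy()
    out = X.copy()
    seed_seq = np.random.SeedSequence(spec.seed)
    for i, child in enumerate(seed_seq.spawn(len(X))):
        rng = np.random.default_rng(child)
        extent = X.shape[2] if spec.orientation == "horizontal" else X.shape[3]
        mask = _stripe_row_mask(extent, spec, rng)
        for c in range(image_channels, X.shape[1]):
            grid = out[i, c] if spec.orientation == "horizontal" else out[i, c].T
            grid = _apply_rows(grid, mask, spec, rng)
            out[i, c] = grid if spec.orientation == "horizontal" else grid.T
    return out


def run_noise_sweep(model, X: np.ndarray, y: np.ndarray, levels,
                    spec_template: NoiseSpec | None = None) -> pd.DataFrame:
    """Macro AUC of a fitted model under increasing heatmap corruption.

    Noise touches only the heatmap channels and only at test time; level 0 is
    always included as the clean reference. Returns a DataFrame with columns
    ``level`` and ``auc_macro`` plus per-class AUCs (NaN where a class has a
    single label value in the test set).
    """
    spec_template = spec_template or NoiseSpec()
    levels = sorted(set(float(l) for l in levels) | {0.0})
    rows = []
    for level in levels:
        spec = replace(spec_template, level=level)
        probs = model.predict_proba(corrupt_stack(X, spec))
        macro, per_class = macro_auc(probs, y)
        rows.append({"level": level, "auc_macro": macro,
                     **{f"auc_class_{k}": v for k, v in enumerate(per_class)}})
    return pd.DataFrame(rows)
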