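"""Training protocol: dataset splitting, the fit loop, early stopping.

The default protocol mirrors a standard fine-tuning recipe: Adam, learning
rate 5e-5, weight decay 1e-3, batch size 32, 20 epochs, an 80/10/10
train/validation/test split, seed 42. The loss is unweighted mean binary
cross-entropy across the independent sigmoid outputs. Early stopping on a
rising validation loss is available but off by default.

Splitting is per-image. On real multi-view data a per-patient split would be
needed to avoid leakage; the phantom generator produces independent cases,
where per-image is correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import GazeFusionClassifier, should_stop, stack_dataset

__all__ = ["TrainConfig", "LossCurves", "split_dataset", "train", "should_stop"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    learning_rate: float = 5e-5
    weight_decay: float = 1e-3
    batch_size: int = 32
    optimizer: str = "adam"
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 42
    early_stopping: bool = False
    patience: int = 3

    def validate(self) -> None:
        if self.epochs < 0:
            raise ValueError(f"epochs must be >= 0, got {self.epochs}")
        for name in ("learning_rate", "weight_decay", "batch_size", "patience"):
            v = getattr(self, name)
            if v <= 0 and not (name == "weight_decay" and v == 0):
                raise ValueError(f"{name} must be positive, got {v}")
        if self.optimizer.lower() != "adam":
            raise ValueError(f"only the adam optimizer is supported, got {self.optimizer!r}")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.split}")
        if any(f < 0 for f in self.split):
            raise ValueError(f"split fractions must be nonnegative, got {self.split}")


@dataclass
class LossCurves:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)


def split_dataset(samples, fractions=(0.8, 0.1, 0.1), seed: int = 42):
    """Seeded disjoint, exhaustive train/val/test partition of a sample list.

    Validation and test sizes are rounded to the nearest integer; the
    remainder goes to train, so 100 samples at 80/10/10 split as (80, 10, 10).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    n = len(samples)
    if n < 3:
        raise ValueError(f"need at least 3 samples to split, got {n}")
    n_val = int(round(n * fractions[1]))
    n_test = int(round(n * fractions[2]))
    if n_val + n_test >= n:
        raise ValueError(f"split {fractions} leaves no training samples for n={n}")
    order = np.random.default_rng(seed).permutation(n)
    test_idx = order[:n_test]
    val_idx = order[n_test : n_test + n_val]
    train_idx = order[n_test + n_val :]
    pick = lambda idx: [samples[i] for i in idx]
    return pick(train_idx), pick(val_idx), pick(test_idx)


def _as_arrays(dataset, include_gaze: bool):
    if dataset is None:
        return None, None
    if isinstance(dataset, tuple) and len(dataset) == 2:
        return np.asarray(dataset[0]), np.asarray(dataset[1])
    return stack_dataset(dataset, include_gaze=include_gaze)


def train(model: GazeFusionClassifier, train_set, val_set=None,
          config: TrainConfig | None = None):
    """Fit a classifier under a training protocol; returns (model, LossCurves).

    ``train_set`` / ``val_set`` are either ``(X, y)`` array pairs or lists of
    phantom samples (heatmaps are then rendered per sample from its own gaze
    table — one reader per image, no cross-reader aggregation).
    """
    config = config or TrainConfig()
    config.validate()
    # Sample lists are stacked as 4-channel fusion input; image-only callers
    # pass (X, y) arrays directly.
    X, y = _as_arrays(train_set, include_gaze=True)
    Xv, yv = _as_arrays(val_set, include_gaze=True)
    model.set_params(epochs=config.epochs, learning_rate=config.learning_rate,
                     weight_decay=config.weight_decay, batch_size=config.batch_size,
                     early_stopping=config.early_stopping, patience=config.patience,
                     random_state=config.seed)
    model.fit(X, y, X_val=Xv, y_val=yv)
    return model, LossCurves(train_loss=list(model.loss_curve_),
                             val_loss=list(model.val_loss_curve_))
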