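"""Gaze-guided multimodal fusion classifier.

The architecture is early fusion: the grayscale radiograph (1 channel) and
the RGB rendering of the expert fixation heatmap (3 channels) are stacked
into a 4-channel input, passed through a learned attention gate (two 1x1
convolutions, ReLU between, sigmoid scores multiplied back onto the input),
then through a shared convolutional backbone, a global average pool and a
fully connected head producing one independent sigmoid logit per abnormality
class (multilabel).

The estimator follows scikit-learn conventions (``fit`` / ``predict`` /
``predict_proba`` / ``decision_function``, ``get_params``/``set_params``,
fitted attributes with trailing underscores) and composes with sklearn
model selection. Training is seeded Adam on mean binary cross-entropy.

Backbones are pluggable small CNNs described as ``(width, stride)`` block
lists; named presets ``"tiny"`` (three 3x3 blocks, feature dim 32) and
``"tiny2"`` (two blocks, feature dim 16) cover testing and the scaled-down
experiments. Setting ``shared_backbone=False`` gives the no-parameter-sharing
baseline: separate image and heatmap branches whose pooled features are
concatenated before the head.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .heatmap import FixationHeatmap, render_fixation_heatmap

__all__ = [
    "BACKBONES",
    "AttentionGateParams",
    "GazeFusionClassifier",
    "build_image_only_model",
    "stack_multimodal",
    "stack_dataset",
    "attention_gate",
    "predict_probs",
]

BACKBONES: dict[str, list[tuple[int, int]]] = {
    "tiny": [(16, 2), (32, 2), (32, 2)],
    "tiny2": [(16, 2), (16, 2)],
}


@dataclass(frozen=True)
class AttentionGateParams:
    """Explicit weights for the two 1x1 convolutions of the attention gate."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    dropout_rate: float = 0.0

    def __post_init__(self):
        if self.W1.ndim != 4 or self.W1.shape[2:] != (1, 1):
            raise ValueError(f"W1 must be (out, in, 1, 1), got {self.W1.shape}")
        if self.W2.ndim != 4 or self.W2.shape[2:] != (1, 1):
            raise ValueError(f"W2 must be (out, in, 1, 1), got {self.W2.shape}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")


def should_stop(val_losses, patience: int) -> bool:
    """Early-stop rule: validation loss strictly rising for `patience` steps."""
    if len(val_losses) < patience + 1:
        return False
    tail = list(val_losses)[-(patience + 1):]
    return all(b > a for a, b in zip(tail, tail[1:]))


def stack_multimodal(image: np.ndarray, heatmap: FixationHeatmap | np.ndarray) -> np.ndarray:
    """Stack grayscale image and heatmap RGB into a (4, H, W) fusion input."""
    img = np.asarray(image, dtype=np.float64)
    rgb = heatmap.rgb if isinstance(heatmap, FixationHeatmap) else np.asarray(heatmap)
    if rgb.ndim == 3 and rgb.shape[2] == 3:  # (H, W, 3) -> (3, H, W)
        rgb = np.moveaxis(rgb, 2, 0)
    if img.ndim != 2 or rgb.shape != (3, *img.shape):
        raise ValueError(
            f"image shape {img.shape} and heatmap rgb shape {rgb.shape} are not a "
            f"matching (H, W) / (3, H, W) pair"
        )
    return np.concatenate([img[None], rgb], axis=0)


def stack_dataset(samples, sigma: float | None = None, duration_weighted: bool = True,
                  include_gaze: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Render per-sample heatmaps and assemble (X, y) arrays from phantom samples.

    ``include_gaze=False`` gives 1-channel image-only inputs for the ablation
    baseline.
    """
    xs, ys = [], []
    for s in samples:
        if include_gaze:
            h, w = s.image.shape
            hm = render_fixation_heatmap(s.gaze, w, h, sigma=sigma,
                                         duration_weighted=duration_weighted)
            xs.append(stack_multimodal(s.image, hm))
        else:
            xs.append(np.asarray(s.image, dtype=np.float64)[None])
        ys.append(s.labels)
    return np.stack(xs), np.stack(ys).astype(np.int8)


def attention_gate(input_features: np.ndarray, params: AttentionGateParams,
                   train_mode: bool = False, seed: int = 0) -> np.ndarray:
    """Functional attention gate with explicit weights.

    Computes ``ReLU(W1 * F + b1)`` -> ``sigmoid(W2 * . + b2)`` (optional
    dropout on the scores in train mode) and returns the input multiplied by
    the score map. A single-channel score map broadcasts over all input
    channels; a C-channel map gates per channel.
    """
    x = np.asarray(input_features, dtype=np.float64)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    c = x.shape[1]
    if params.W1.shape[1] != c:
        raise ValueError(
            f"gate expects {params.W1.shape[1]} input channels (W1 shape "
            f"{params.W1.shape}), got input with {c} channels")
    out_ch = params.W2.shape[0]
    if out_ch not in (1, c):
        raise ValueError(f"score-map channels must be 1 or {c}, got {out_ch}")
    gate = nn.AttentionGate(c, hidden_ch=params.W1.shape[0],
                            per_channel=(out_ch == c), dropout=params.dropout_rate)
    gate.conv1.params["W"] = np.asarray(params.W1, dtype=np.float64)
    gate.conv1.params["b"] = np.asarray(params.b1, dtype=np.float64)
    gate.conv2.params["W"] = np.asarray(params.W2, dtype=np.float64)
    gate.conv2.params["b"] = np.asarray(params.b2, dtype=np.float64)
    gate.reseed(np.random.default_rng(seed))
    out = gate.forward(x, train=train_mode)
    return out[0] if squeeze else out


def predict_probs(logits: np.ndarray, threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Sigmoid probabilities and thresholded binary labels from logits."""
    probs = nn.sigmoid(np.asarray(logits, dtype=np.float64))
    return probs, (probs >= threshold).astype(np.int8)


def _resolve_backbone(backbone) -> list[tuple[int, int]]:
    if isinstance(backbone, str):
        try:
            return BACKBONES[backbone]
        except KeyError:
            raise ValueError(f"unknown backbone {backbone!r}; known: {sorted(BACKBONES)}")
    return [(int(w), int(s)) for w, s in backbone]


class GazeFusionClassifier(ClassifierMixin, BaseEstimator):
    """Multilabel CNN classifier over stacked radiograph + fixation-heatmap input.

    Parameters
    ----------
    backbone : str or list of (width, stride)
        Convolutional backbone preset name or explicit 3x3 block list.
    use_gate : bool
        Apply the attention gate to the stacked input before the backbone.
    shared_backbone : bool
        ``True`` (default): single unified backbone over all channels.
        ``False``: the no-shared-parameters baseline with separate image and
        heatmap branches (requires 4-channel input; the gate is not used).
    gate_hidden, gate_per_channel, gate_dropout
        Attention-gate width, score-map broadcasting mode, and train-time
        dropout on the sigmoid scores.
    epochs, learning_rate, weight_decay, batch_size
        Adam training protocol. Defaults mirror a fine-tuning recipe
        (20 epochs, lr 5e-5, weight decay 1e-3, batch 32); training a tiny
        backbone from scratch wants a larger rate, e.g. 2e-3.
    threshold : float
        Per-class decision cutoff applied to sigmoid probabilities.
    early_stopping, patience
        Optional halt when validation loss rises for ``patience``
        consecutive epochs (off by default).
    random_state : int
        Seeds initialization, batch shuffling and dropout.

    Attributes
    ----------
    network_ : the fitted network
    loss_curve_, val_loss_curve_ : per-epoch mean losses
    n_classes_, classes_ : label-space description
    feature_dim_ : backbone feature dimension D
    cam_layer_ : default hooked layer name for class-activation mapping
    """

    def __init__(self, backbone="tiny", use_gate=True, shared_backbone=True,
                 gate_hidden=8, gate_per_channel=False, gate_dropout=0.1,
                 epochs=20, learning_rate=5e-5, weight_decay=1e-3, batch_size=32,
                 threshold=0.5, early_stopping=False, patience=3,
                 random_state=42, verbose=0):
        self.backbone = backbone
        self.use_gate = use_gate
        self.shared_backbone = shared_backbone
        self.gate_hidden = gate_hidden
        self.gate_per_channel = gate_per_channel
        self.gate_dropout = gate_dropout
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.threshold = threshold
        self.early_stopping = early_stopping
        self.patience = patience
        self.random_state = random_state
        self.verbose = verbose

    # -- network construction -------------------------------------------------

    def _build_backbone(self, in_ch: int, prefix: str = "") -> list[tuple[str, nn.Layer]]:
        layers: list[tuple[str, nn.Layer]] = []
        c = in_ch
        for i, (width, stride) in enumerate(_resolve_backbone(self.backbone), start=1):
            layers.append((f"{prefix}conv{i}", nn.Conv2d(c, width, kernel=3, stride=stride, pad=1)))
            layers.append((f"{prefix}relu{i}", nn.ReLU()))
            c = width
        return layers

    def _build_network(self, in_ch: int, n_classes: int):
        blocks = _resolve_backbone(self.backbone)
        feat = blocks[-1][0]
        # inputs live in [0, 1]; shift to zero mean so ReLU features train well
        center = ("center", nn.Shift(-0.5))
        if not self.shared_backbone:
            if in_ch != 4:
                raise ValueError(
                    f"the dual-branch baseline needs a 4-channel input, got {in_ch} channels")
            image_branch = nn.Sequential(
                [("center", nn.Shift(-0.5))] + self._build_backbone(1)
                + [("gap", nn.GlobalAvgPool())])
            gaze_branch = nn.Sequential(
                [("center", nn.Shift(-0.5))] + self._build_backbone(3)
                + [("gap", nn.GlobalAvgPool())])
            head = nn.Linear(2 * feat, n_classes)
            return nn.DualBranchNetwork(image_branch, gaze_branch, head), 2 * feat, None
        layers: list[tuple[str, nn.Layer]] = [center]
        if self.use_gate:
            layers.append(("gate", nn.AttentionGate(in_ch, hidden_ch=self.gate_hidden,
                                                    per_channel=self.gate_per_channel,
                                                    dropout=self.gate_dropout)))
        layers += self._build_backbone(in_ch)
        cam_layer = layers[-1][0]  # final backbone activation
        layers += [("gap", nn.GlobalAvgPool()), ("fc", nn.Linear(feat, n_classes))]
        return nn.Sequential(layers), feat, cam_layer

    # -- sklearn API ----------------------------------------------------------

    def _validate_xy(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 4:
            raise ValueError(f"X must be (n_samples, channels, H, W), got shape {X.shape}")
        if y is None:
            return X
        y = np.asarray(y)
        if y.ndim != 2 or y.shape[0] != X.shape[0]:
            raise ValueError(f"y must be (n_samples, n_classes) binary, got shape {y.shape}")
        return X, y.astype(np.float64)

    def fit(self, X, y, X_val=None, y_val=None):
        X, y = self._validate_xy(X, y)
        if X_val is not None:
            X_val, y_val = self._validate_xy(X_val, y_val)
        n, in_ch = X.shape[:2]
        self.n_classes_ = y.shape[1]
        self.classes_ = np.arange(self.n_classes_)
        self.n_channels_ = in_ch

        self.network_, self.feature_dim_, self.cam_layer_ = self._build_network(
            in_ch, self.n_classes_)
        init_rng = np.random.default_rng(self.random_state)
        self.network_.init_params(init_rng)
        shuffle_rng = np.random.default_rng(
            np.random.default_rng(self.random_state + 1).integers(2**31))

        if self.epochs < 0:
            raise ValueError(f"epochs must be >= 0, got {self.epochs}")
        opt = nn.Adam(lr=self.learning_rate, weight_decay=self.weight_decay)
        self.loss_curve_: list[float] = []
        self.val_loss_curve_: list[float] = []
        for epoch in range(self.epochs):
            order = shuffle_rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                logits = self.network_.forward(X[idx], train=True)
                loss, dlogits = nn.bce_with_logits(logits, y[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged: non-finite loss {loss} at epoch {epoch}, "
                        f"batch starting at {start} (lr={self.learning_rate})")
                self.network_.backward(dlogits)
                opt.step(self.network_)
                epoch_losses.append(loss)
            self.loss_curve_.append(float(np.mean(epoch_losses)))

            if X_val is not None and len(X_val):
                val_logits = self.network_.forward(X_val, train=False)
                val_loss, _ = nn.bce_with_logits(val_logits, y_val)
                self.val_loss_curve_.append(float(val_loss))
                if self.early_stopping and should_stop(self.val_loss_curve_, self.patience):
                    if self.verbose:
                        print(f"early stop at epoch {epoch + 1}: val loss rising "
                              f"{self.patience} epochs")
                    break
            if self.verbose:
                msg = f"epoch {epoch + 1}/{self.epochs} train loss {self.loss_curve_[-1]:.4f}"
                if self.val_loss_curve_:
                    msg += f" val loss {self.val_loss_curve_[-1]:.4f}"
                print(msg)
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        X = self._validate_xy(X)
        if X.shape[1] != self.n_channels_:
            raise ValueError(
                f"model was fitted on {self.n_channels_}-channel input, got {X.shape[1]}")
        out = []
        for start in range(0, len(X), 256):  # bounded memory
            out.append(self.network_.forward(X[start : start + 256], train=False))
        return np.concatenate(out, axis=0)

    def predict_proba(self, X) -> np.ndarray:
        """Per-class sigmoid probabilities (independent labels; rows need not sum to 1)."""
        return nn.sigmoid(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= self.threshold).astype(np.int8)

    def n_parameters(self) -> int:
        check_is_fitted(self, "network_")
        return self.network_.n_params()

    def attention_map(self, X) -> np.ndarray:
        """Eval-mode attention score maps for a batch (shared-backbone + gate only)."""
        check_is_fitted(self, "network_")
        if not (self.shared_backbone and self.use_gate):
            raise ValueError("this model has no attention gate")
        X = self._validate_xy(X)
        return self.network_["gate"].attention_weights(X - 0.5)


def build_image_only_model(**kwargs) -> GazeFusionClassifier:
    """Ablation baseline: plain CXR-only classifier (1-channel input, no gate)."""
    kwargs.setdefault("use_gate", False)
    return GazeFusionClassifier(**kwargs)
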