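"""Single-head band attention, fusion, classifier, and the training loop.

The five per-band feature vectors from the backbone are stacked into
X in R^{N_b x D} (D = number of channels) and passed through one
query-key-value self-attention head,

    Q = X W_Q,  K = X W_K,  V = X W_V,
    A = softmax(Q K^T / sqrt(d_k)),            (row-wise)
    X' = Linear(A V),

followed by a fusion that keeps both band-specific detail and global
spectral context:

    F_concat = flatten(X'),  F_global = mean over bands of X',
    Z_final  = [F_concat ; F_global]  in R^{N_b D + D}.

A deliberately single-head design keeps the parameter count small for
limited EEG datasets. The classifier is two dense layers with dropout, and
training uses Adam with label-smoothed cross-entropy; one integer seed
controls parameter initialization, batch order and dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbone import BackboneConfig, BandBackbone
from .nn import (Adam, Linear, Module, Parameter, Tensor, concat,
                 clip_grad_norm, dropout)

__all__ = [
    "AttentionParams", "BandAttention", "Classifier", "EmotionNet",
    "TrainConfig", "TrainHistory", "attention_map", "refine_and_fuse",
    "classify", "label_smooth_targets", "cross_entropy_smoothed",
    "train_model", "predict",
]


@dataclass(frozen=True)
class AttentionParams:
    """Dimension and regularization settings for the fusion head."""

    n_bands: int = 5
    feature_dim: int = 62      # D: per-band feature length (channel count)
    d_k: int | None = None     # default D
    d_v: int | None = None     # default D
    dropout_rate: float = 0.1
    label_smoothing: float = 0.1

    def __post_init__(self) -> None:
        if self.n_bands < 1 or self.feature_dim < 1:
            raise ValueError("n_bands and feature_dim must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if not (0.0 <= self.label_smoothing < 1.0):
            raise ValueError("label_smoothing must lie in [0, 1)")

    @property
    def dk(self) -> int:
        return self.d_k if self.d_k is not None else self.feature_dim

    @property
    def dv(self) -> int:
        return self.d_v if self.d_v is not None else self.feature_dim

    @property
    def fused_dim(self) -> int:
        return self.n_bands * self.feature_dim + self.feature_dim


class BandAttention(Module):
    """Exactly one (W_Q, W_K, W_V) projection triple — single-head by design."""

    def __init__(self, params: AttentionParams, rng: np.random.Generator):
        self.params = params
        d = params.feature_dim
        self.w_query = Parameter(
            (rng.standard_normal((d, params.dk)) / np.sqrt(d)).astype(np.float32))
        self.w_key = Parameter(
            (rng.standard_normal((d, params.dk)) / np.sqrt(d)).astype(np.float32))
        self.w_value = Parameter(
            (rng.standard_normal((d, params.dv)) / np.sqrt(d)).astype(np.float32))
        self.out_proj = Linear(params.dv, d, rng)

    def attention_map(self, x: Tensor) -> Tensor:
        """A = softmax(Q K^T / sqrt(d_k)), rows summing to one."""
        q = x @ self.w_query
        k = x @ self.w_key
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.params.dk))
        return scores.softmax(axis=-1)

    def refine_and_fuse(self, x: Tensor, a: Tensor) -> Tensor:
        """Z_final = [flatten(Linear(A V)) ; mean over bands], length N_b*D + D."""
        v = x @ self.w_value
        x_ref = self.out_proj(a @ v)                     # (..., N_b, D)
        lead = x_ref.shape[:-2]
        nb, d = x_ref.shape[-2], x_ref.shape[-1]
        f_concat = x_ref.reshape(*lead, nb * d)
        f_global = x_ref.mean(axis=-2)
        return concat([f_concat, f_global], axis=-1)

    def __call__(self, x: Tensor) -> Tensor:
        return self.refine_and_fuse(x, self.attention_map(x))


class Classifier(Module):
    """Two dense layers with dropout between; logits over n_classes."""

    def __init__(self, in_dim: int, n_classes: int, rng: np.random.Generator,
                 hidden: int = 64, dropout_rate: float = 0.1):
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        self.fc1 = Linear(in_dim, hidden, rng)
        self.fc2 = Linear(hidden, n_classes, rng)
        self.dropout_rate = dropout_rate
        self._rng = rng

    def __call__(self, z: Tensor) -> Tensor:
        h = self.fc1(z).relu()
        h = dropout(h, self.dropout_rate, self._rng, self.training)
        return self.fc2(h)


class EmotionNet(Module):
    """Full model: five band backbones -> band attention fusion -> classifier.

    Input (B, channels, T, n_bands); output logits (B, n_classes).
    """

    def __init__(self, n_classes: int = 3,
                 backbone_config: BackboneConfig | None = None,
                 attention_params: AttentionParams | None = None,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.backbone_config = backbone_config or BackboneConfig()
        self.attention_params = attention_params or AttentionParams(
            feature_dim=self.backbone_config.n_nodes)
        if self.attention_params.feature_dim != self.backbone_config.n_nodes:
            raise ValueError("attention feature_dim must equal node count")
        self.band_backbones = [
            BandBackbone(self.backbone_config, rng)
            for _ in range(self.attention_params.n_bands)
        ]
        self.band_attention = BandAttention(self.attention_params, rng)
        self.classifier = Classifier(
            self.attention_params.fused_dim, n_classes, rng,
            dropout_rate=self.attention_params.dropout_rate)
        self.n_classes = n_classes
        # input standardization constants, fit on the training set
        self.input_mean: float = 0.0
        self.input_std: float = 1.0

    def band_matrix(self, x: Tensor) -> Tensor:
        """(B, channels, T, bands) -> stacked band features (B, N_b, D)."""
        data = (x.data - self.input_mean) / self.input_std
        feats = []
        for b, backbone in enumerate(self.band_backbones):
            # (B, channels, T) slice of band b
            xb = Tensor(np.ascontiguousarray(data[:, :, :, b]),
                        requires_grad=False)
            feats.append(backbone(xb).reshape(x.shape[0], 1, -1))
        return concat(feats, axis=1)

    def __call__(self, x: Tensor) -> Tensor:
        z = self.band_attention(self.band_matrix(x))
        return self.classifier(z)


# ---------------------------------------------------------------------------
# array-level contract functions


def attention_map(x: np.ndarray, head: BandAttention) -> np.ndarray:
    """Row-stochastic inter-band attention map for a (N_b, D) feature matrix."""
    return head.attention_map(Tensor(np.asarray(x, dtype=float))).data


def refine_and_fuse(x: np.ndarray, a: np.ndarray,
                    head: BandAttention) -> np.ndarray:
    """Fused representation Z_final of length N_b*D + D."""
    xt = Tensor(np.asarray(x, dtype=float))
    at = Tensor(np.asarray(a, dtype=float))
    if at.shape[-1] != xt.shape[-2] or at.shape[-2] != xt.shape[-2]:
        raise ValueError(
            f"attention map {at.shape} inconsistent with features {xt.shape}")
    return head.refine_and_fuse(xt, at).data


def classify(z_final: np.ndarray, classifier: Classifier
             ) -> tuple[np.ndarray, np.ndarray]:
    """Logits and argmax labels for fused feature vectors (batched or single)."""
    z = np.atleast_2d(np.asarray(z_final, dtype=float))
    logits = classifier(Tensor(z)).data
    return logits, logits.argmax(axis=-1)


def label_smooth_targets(labels: np.ndarray, n_classes: int,
                         epsilon: float = 0.1) -> np.ndarray:
    """Smoothed targets (1 - eps) * onehot + eps / n_classes."""
    labels = np.asarray(labels, dtype=int)
    onehot = np.eye(n_classes)[labels]
    return (1.0 - epsilon) * onehot + epsilon / n_classes


def cross_entropy_smoothed(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy against (smoothed) target distributions."""
    logp = logits.log_softmax(axis=-1)
    return -(logp * Tensor(np.asarray(targets, dtype=logits.data.dtype))).sum() \
        * (1.0 / logits.shape[0])


# ---------------------------------------------------------------------------
# training


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer settings; defaults follow the reference recipe."""

    learning_rate: float = 0.001
    batch_size: int = 64
    epochs: int = 200
    label_smoothing: float = 0.1
    grad_clip_norm: float = 5.0   # global-norm gradient clipping; <=0 disables
    seed: int = 0

    def manifest(self) -> dict:
        return {"lr": self.learning_rate, "batch": self.batch_size,
                "epochs": self.epochs,
                "label_smoothing": self.label_smoothing, "seed": self.seed}


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)


def train_model(features: np.ndarray, labels: np.ndarray,
                config: TrainConfig = TrainConfig(),
                model: EmotionNet | None = None,
                n_classes: int | None = None
                ) -> tuple[EmotionNet, TrainHistory]:
    """Train the full backbone + attention model on a feature tensor.

    ``features`` has shape (trials, channels, T, bands). Deterministic given
    ``config.seed`` (initialization, batch order and dropout all derive from
    it). Raises on single-class data.
    """
    x = np.asarray(features, dtype=np.float32)
    y = np.asarray(labels, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    n_cls = n_classes if n_classes is not None else int(classes.max()) + 1

    if model is None:
        _, n_ch, t, nb = x.shape
        bc = BackboneConfig(n_nodes=n_ch, top_k=min(10, n_ch))
        ap = AttentionParams(n_bands=nb, feature_dim=n_ch)
        model = EmotionNet(n_classes=n_cls, backbone_config=bc,
                           attention_params=ap, seed=config.seed)
    # standardize inputs with training-set statistics (stored on the model)
    model.input_mean = float(x.mean())
    model.input_std = float(max(x.std(), 1e-8))
    rng = np.random.default_rng(config.seed + 1)
    model.classifier._rng = np.random.default_rng(config.seed + 2)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    targets_all = label_smooth_targets(y, n_cls, config.label_smoothing)

    history = TrainHistory()
    n = len(y)
    model.train()
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, correct = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model(Tensor(x[idx]))
            loss = cross_entropy_smoothed(logits, targets_all[idx])
            opt.zero_grad()
            loss.backward()
            if config.grad_clip_norm > 0:
                clip_grad_norm(opt.params, config.grad_clip_norm)
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
            correct += int((logits.data.argmax(axis=-1) == y[idx]).sum())
        history.loss.append(epoch_loss / n)
        history.accuracy.append(correct / n)
    model.eval()
    return model, history


def predict(model: EmotionNet, features: np.ndarray,
            batch_size: int = 64) -> np.ndarray:
    """Predicted labels for a feature tensor (eval mode, deterministic)."""
    model.eval()
    x = np.asarray(features, dtype=np.float32)
    out = []
    for start in range(0, len(x), batch_size):
        logits = model(Tensor(x[start : start + batch_size]))
        out.append(logits.data.argmax(axis=-1))
    return np.concatenate(out) if out else np.empty(0, dtype=int)
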