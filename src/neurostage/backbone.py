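"""Backbone feature extraction and model assembly.

A feature extractor maps resized RGB images to high-level activation maps
``Z`` (``H x W x C``); the attention block refines them and global average
pooling yields the feature vector handed to the classifier.

Two backbones are exposed:

* ``tiny_test`` — a small, self-contained stack of three stride-2 3x3
  convolutions with seeded random weights (ReLU between layers), producing 32
  channels at 1/8 of the input resolution.  It needs no downloads and is the
  default for synthetic-data runs and tests.
* ``inception_v3`` — the 299x299-input pretrained network the full-scale
  pipeline targets.  Its weights cannot be materialised offline, so
  requesting it without a weights file raises an actionable error pointing at
  ``tiny_test``.

Head fine-tuning updates only the parts with analytic gradients: the dense
softmax head and each attention head's fusion scalars ``w1``/``w2`` (the
block is linear in them, see :mod:`neurostage.attention`).  The backbone and
attention projections stay frozen.  Adam is used as the optimiser.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import transform as sktransform

from . import attention
from .data import DatasetManifest, load_image
from .exceptions import ConfigError, DataError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "BackboneSpec",
    "HeadTrainConfig",
    "TinyConvExtractor",
    "build_feature_extractor",
    "AttentionClassifier",
    "assemble_model",
    "finetune_head",
]


@dataclass(frozen=True)
class BackboneSpec:
    """Which backbone to use and how to feed it."""

    name: str = "tiny_test"
    input_size: tuple = (64, 64)
    feature_layer: str = "final_conv"
    frozen: bool = True

    def __post_init__(self) -> None:
        if self.name == "inception_v3" and tuple(self.input_size) != (299, 299):
            raise ConfigError("inception_v3 requires input_size (299, 299)")
        if self.name == "tiny_test" and min(self.input_size) < 32:
            raise ConfigError("tiny_test requires input_size >= 32 in both dimensions")


@dataclass(frozen=True)
class HeadTrainConfig:
    """Fine-tuning schedule for the attention fusion scalars and softmax head."""

    learning_rate: float = 1e-4
    epochs: int = 5
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ParameterError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ParameterError("epochs and batch_size must be >= 1")


def _ensure_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = np.repeat(image[:, :, None], 3, axis=2)
    return image


def _conv2d_stride2(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded 3x3 convolution with stride 2 (output = ceil(in / 2))."""
    h, w_in, _ = x.shape
    xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(0, 1))
    # windows: (h, w_in, Cin, 3, 3) -> stride-2 subsample of positions
    windows = windows[0:h:2, 0:w_in:2]
    out = np.einsum("ijcxy,xyck->ijk", windows, w, optimize=True)
    return out + b


class TinyConvExtractor:
    """Three stride-2 3x3 conv layers (3->16->32->32 channels) with ReLU,
    seeded He-initialised weights, no training.  A ``(H, W, 3)`` input yields
    a ``(ceil(H/8), ceil(W/8), 32)`` feature map."""

    channels = 32

    def __init__(self, spec: BackboneSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        widths = [3, 16, 32, 32]
        self.weights = []
        self.biases = []
        for cin, cout in zip(widths[:-1], widths[1:]):
            fan_in = 9 * cin
            self.weights.append(rng.normal(0, np.sqrt(2.0 / fan_in), size=(3, 3, cin, cout)))
            self.biases.append(np.zeros(cout))

    def __call__(self, image: np.ndarray) -> np.ndarray:
        """Resize to ``spec.input_size`` and run the conv stack.  The input
        array is never modified."""
        x = _ensure_rgb(image)
        if x.shape[:2] != tuple(self.spec.input_size):
            x = sktransform.resize(
                x, self.spec.input_size, order=1, mode="reflect", anti_aliasing=True
            )
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            x = _conv2d_stride2(x, w, b)
            if i < len(self.weights) - 1:
                x = np.maximum(x, 0.0)
        return np.maximum(x, 0.0)


def build_feature_extractor(spec: BackboneSpec, seed: int = 0, weights_path=None):
    """Return a callable image -> feature map for the requested backbone."""
    if spec.name == "tiny_test":
        return TinyConvExtractor(spec, seed=seed)
    if spec.name == "inception_v3":
        raise ConfigError(
            "inception_v3 pretrained weights are not available in this "
            "installation (no deep-learning runtime and no bundled weights). "
            "Use --backbone tiny_test for synthetic runs, or provide a "
            "converted weights file and a runtime that can load it."
            + (f" (weights_path={weights_path} could not be used)" if weights_path else "")
        )
    raise ConfigError(f"unknown backbone {spec.name!r}; choose tiny_test or inception_v3")


@dataclass
class AttentionClassifier:
    """Backbone + attention block + dense softmax head (+ ELM downstream).

    ``use_gsa=False`` bypasses the attention block (ablation), in which case
    the pooled backbone features feed the head directly.
    """

    extractor: object
    heads: list
    gsa_config: attention.GSAConfig | None
    n_classes: int
    use_gsa: bool = True
    head_weights: np.ndarray | None = None  # C x k
    head_bias: np.ndarray | None = None  # k
    class_labels: list = field(default_factory=list)

    @property
    def feature_dim(self) -> int:
        return self.extractor.channels

    def feature_map(self, image: np.ndarray) -> np.ndarray:
        return self.extractor(image)

    def refined_map(self, image: np.ndarray) -> np.ndarray:
        Z = self.feature_map(image)
        if not self.use_gsa:
            return Z
        out, _ = attention.gsa_forward(Z, self.heads, self.gsa_config)
        return out

    def features(self, images) -> np.ndarray:
        """Pooled feature vectors (n x C) for a sequence of images."""
        return np.stack([self.refined_map(img).mean(axis=(0, 1)) for img in images])

    def head_logits(self, feats: np.ndarray) -> np.ndarray:
        return feats @ self.head_weights + self.head_bias

    def attention_diagnostics(self, image: np.ndarray) -> attention.AttentionDiagnostics:
        if not self.use_gsa:
            raise ConfigError("attention diagnostics require use_gsa=True")
        _, diags = attention.gsa_forward(self.feature_map(image), self.heads, self.gsa_config)
        return diags


def assemble_model(
    extractor,
    gsa: attention.GSAConfig | int | None,
    n_classes: int,
    seed: int = 0,
    use_gsa: bool = True,
) -> AttentionClassifier:
    """Compose image -> backbone -> attention -> pooled features -> head.

    ``gsa`` may be a prebuilt :class:`~neurostage.attention.GSAConfig` (with
    matching head list supplied separately via ``init_gsa``) or an integer
    head count, in which case heads are initialised here from ``seed``.
    """
    if n_classes < 2:
        raise ParameterError(f"n_classes must be >= 2, got {n_classes}")
    channels = extractor.channels
    heads: list = []
    config = None
    if use_gsa:
        if gsa is None:
            gsa = 4
        if isinstance(gsa, int):
            n_heads, divisor = gsa, 8
        else:
            n_heads, divisor = gsa.heads, gsa.reduction_divisor
        heads, config = attention.init_gsa(
            channels, seed=seed, heads=n_heads, reduction_divisor=divisor
        )
    rng = np.random.default_rng(seed + 1)
    head_w = rng.normal(0, 1.0 / np.sqrt(channels), size=(channels, n_classes))
    return AttentionClassifier(
        extractor=extractor,
        heads=heads,
        gsa_config=config,
        n_classes=n_classes,
        use_gsa=use_gsa,
        head_weights=head_w,
        head_bias=np.zeros(n_classes),
    )


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _pooled_path_contributions(model: AttentionClassifier, image: np.ndarray):
    """Pooled per-head path vectors so the feature vector is linear in the
    fusion scalars:  f = sum_i (w1_i u_i + w2_i v_i) + pooled output bias.

    Returns (U, V) with shape (h, C) each.
    """
    Z = model.feature_map(image)
    h, w, c = Z.shape
    U = np.zeros((len(model.heads), c))
    Vv = np.zeros((len(model.heads), c))
    for i, params in enumerate(model.heads):
        Q, K, V = attention.project_qkv(Z, params)
        Z_sp, z_prime = attention.spatial_attention(Q, K, Z)
        Z_ch, _ = attention.channel_attention(
            z_prime, V, params.channel_expand, params.expand_bias, Z
        )
        w_slice = model.gsa_config.output_proj[i * c : (i + 1) * c, :]
        U[i] = Z_sp.mean(axis=(0, 1)) @ w_slice
        Vv[i] = Z_ch.mean(axis=(0, 1)) @ w_slice
    return U, Vv


class _Adam:
    def __init__(self, shapes, lr):
        self.lr = lr
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            out.append(p - self.lr * mhat / (np.sqrt(vhat) + eps))
        return out


def finetune_head(
    model: AttentionClassifier, data: DatasetManifest, cfg: HeadTrainConfig
) -> dict:
    """Train the softmax head (and, with attention enabled, the per-head
    fusion scalars) by Adam on cross-entropy over the manifest's images.

    The backbone and attention projections are frozen, so the per-image
    attention-path contributions are computed once and training is linear in
    the updated parameters.  Returns a history dict with per-epoch loss and
    accuracy; the model is updated in place.  Deterministic given ``cfg.seed``.
    """
    if data.total == 0:
        raise DataError("empty dataset")
    labels = list(data.classes)
    model.class_labels = labels
    images, y = [], []
    for ci, label in enumerate(labels):
        for path in data.files[label]:
            images.append(load_image(path))
            y.append(ci)
    y = np.asarray(y)
    n = len(images)
    onehot = np.eye(len(labels))[y]

    if model.use_gsa:
        UV = [_pooled_path_contributions(model, img) for img in images]
        U = np.stack([u for u, _ in UV])  # n x h x C
        V = np.stack([v for _, v in UV])
        bias_term = model.gsa_config.output_bias if model.gsa_config.output_bias is not None else 0.0
        w1 = np.array([p.w1 for p in model.heads], dtype=np.float64)
        w2 = np.array([p.w2 for p in model.heads], dtype=np.float64)
    else:
        pooled = np.stack([model.feature_map(img).mean(axis=(0, 1)) for img in images])

    W, b = model.head_weights.copy(), model.head_bias.copy()
    if model.use_gsa:
        opt = _Adam([W.shape, b.shape, w1.shape, w2.shape], cfg.learning_rate)
    else:
        opt = _Adam([W.shape, b.shape], cfg.learning_rate)

    rng = np.random.default_rng(cfg.seed)
    history = {"loss": [], "accuracy": []}
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            if model.use_gsa:
                feats = (
                    np.einsum("h,nhc->nc", w1, U[idx])
                    + np.einsum("h,nhc->nc", w2, V[idx])
                    + bias_term
                )
            else:
                feats = pooled[idx]
            logits = feats @ W + b
            probs = _softmax(logits)
            batch_y = onehot[idx]
            eps = 1e-12
            epoch_loss += -np.sum(batch_y * np.log(probs + eps))
            correct += int(np.sum(np.argmax(probs, axis=1) == y[idx]))
            delta = (probs - batch_y) / len(idx)  # dL/dlogits (mean CE)
            gW = feats.T @ delta
            gb = delta.sum(axis=0)
            dfeats = delta @ W.T
            if model.use_gsa:
                gw1 = np.einsum("nc,nhc->h", dfeats, U[idx])
                gw2 = np.einsum("nc,nhc->h", dfeats, V[idx])
                W, b, w1, w2 = opt.step([W, b, w1, w2], [gW, gb, gw1, gw2])
            else:
                W, b = opt.step([W, b], [gW, gb])
        history["loss"].append(epoch_loss / n)
        history["accuracy"].append(correct / n)

    model.head_weights, model.head_bias = W, b
    if model.use_gsa:
        for i, params in enumerate(model.heads):
            params.w1 = float(w1[i])
            params.w2 = float(w2[i])
    logger.info(
        "fine-tune: loss %.4f -> %.4f, accuracy %.3f",
        history["loss"][0], history["loss"][-1], history["accuracy"][-1],
    )
    return history
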