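"""Multi-head generalized self-attention (GSA) over CNN feature maps.

Each head combines two complementary attention paths computed from 1x1
projections of the input map ``Z`` (shape ``H x W x C``):

* a *spatial* path — the globally pooled query is matched against the keys,
  ``Z' = softmax(Q K^T)`` over the ``HW`` positions (no temperature
  scaling), and ``Z`` is reweighted position-wise by ``Z'``;
* a *channel* path — ``Z'`` aggregates the values into a ``C'`` summary,
  which a 1x1 convolution expands back to ``C`` channels and a sigmoid turns
  into per-channel gates ``Z''`` in ``(0, 1)`` applied to ``Z``.

The two paths are fused per head by trainable scalars,
``Z_gs = w1 * Z_sp + w2 * Z_ch``; head outputs are concatenated along
channels and a final 1x1 convolution maps ``h*C`` back to ``C``, so the
block preserves the input shape.  The channel bottleneck is
``C' = max(1, C // reduction_divisor)`` with divisor 8 by default, and the
default head count is 4.

Because the block is linear in each head's fusion scalars, their gradients
are available in closed form (:func:`fusion_scalar_gradients`), which is
what head fine-tuning updates.

Feature maps are plain ``float64`` numpy arrays; spatial flattening is
row-major (row ``r = y * W + x``) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ConfigError, ShapeError

__all__ = [
    "GSAHeadParams",
    "GSAConfig",
    "AttentionDiagnostics",
    "init_head",
    "init_gsa",
    "project_qkv",
    "spatial_attention",
    "channel_attention",
    "fuse_head",
    "gsa_forward",
    "fusion_scalar_gradients",
]


def reduced_channels(channels: int, reduction_divisor: int = 8) -> int:
    """Bottleneck width ``C' = max(1, floor(C / divisor))``."""
    return max(1, channels // reduction_divisor)


@dataclass
class GSAHeadParams:
    """Parameters of one GSA head.

    The four projections are 1x1 convolutions stored as dense matrices:
    ``query/key/value_proj`` map ``C -> C'`` and ``channel_expand`` maps
    ``C' -> C``.  ``w1``/``w2`` weight the spatial and channel paths.
    """

    query_proj: np.ndarray
    key_proj: np.ndarray
    value_proj: np.ndarray
    channel_expand: np.ndarray
    query_bias: np.ndarray
    key_bias: np.ndarray
    value_bias: np.ndarray
    expand_bias: np.ndarray
    w1: float = 0.5
    w2: float = 0.5

    @property
    def channels(self) -> int:
        return self.query_proj.shape[0]

    @property
    def reduced(self) -> int:
        return self.query_proj.shape[1]


@dataclass
class GSAConfig:
    """Block-level configuration: head count, channel-reduction divisor and
    the output 1x1 convolution mapping ``h*C -> C``."""

    heads: int = 4
    reduction_divisor: int = 8
    output_proj: np.ndarray | None = None
    output_bias: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.heads < 1:
            raise ConfigError(f"heads must be >= 1, got {self.heads}")
        if self.reduction_divisor < 1:
            raise ConfigError(
                f"reduction_divisor must be >= 1, got {self.reduction_divisor}"
            )


@dataclass
class AttentionDiagnostics:
    """Per-head attention summaries: spatial simplex weights (each a length
    ``HW`` vector summing to 1) and sigmoid channel gates in ``(0, 1)``."""

    spatial_weights: list
    channel_gates: list


def _fan_in_normal(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    return rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, n_out))


def init_head(
    channels: int, rng: np.random.Generator, reduction_divisor: int = 8
) -> GSAHeadParams:
    """Fan-in-scaled random projections, zero biases, ``w1 = w2 = 0.5``."""
    reduced = reduced_channels(channels, reduction_divisor)
    return GSAHeadParams(
        query_proj=_fan_in_normal(rng, channels, reduced),
        key_proj=_fan_in_normal(rng, channels, reduced),
        value_proj=_fan_in_normal(rng, channels, reduced),
        channel_expand=_fan_in_normal(rng, reduced, channels),
        query_bias=np.zeros(reduced),
        key_bias=np.zeros(reduced),
        value_bias=np.zeros(reduced),
        expand_bias=np.zeros(channels),
    )


def init_gsa(
    channels: int, seed: int, heads: int = 4, reduction_divisor: int = 8
) -> tuple[list[GSAHeadParams], GSAConfig]:
    """Seeded initialization of ``heads`` independent heads plus the output
    projection; all randomness flows from ``seed``."""
    rng = np.random.default_rng(seed)
    head_params = [init_head(channels, rng, reduction_divisor) for _ in range(heads)]
    config = GSAConfig(
        heads=heads,
        reduction_divisor=reduction_divisor,
        output_proj=_fan_in_normal(rng, heads * channels, channels),
        output_bias=np.zeros(channels),
    )
    return head_params, config


def _check_map(Z: np.ndarray) -> np.ndarray:
    Z = np.asarray(Z, dtype=np.float64)
    if Z.ndim != 3:
        raise ShapeError(f"feature map must be H x W x C, got shape {Z.shape}")
    return Z


def project_qkv(
    Z: np.ndarray, params: GSAHeadParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project the map to the pooled query ``Q`` (``1 x C'``) and the key and
    value matrices ``K``, ``V`` (``HW x C'``, row-major flattening)."""
    Z = _check_map(Z)
    h, w, c = Z.shape
    if c != params.channels:
        raise ShapeError(f"map has {c} channels but head expects {params.channels}")
    flat = Z.reshape(h * w, c)
    q_map = flat @ params.query_proj + params.query_bias
    Q = q_map.mean(axis=0, keepdims=True)
    K = flat @ params.key_proj + params.key_bias
    V = flat @ params.value_proj + params.value_bias
    return Q, K, V


def spatial_attention(
    Q: np.ndarray, K: np.ndarray, Z: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Softmax spatial weights ``Z' = softmax(Q K^T)`` over positions and the
    reweighted map ``Z_sp = reshape(Z') * Z``.  No temperature scaling is
    applied to the logits."""
    Z = _check_map(Z)
    h, w, _ = Z.shape
    Q = np.atleast_2d(np.asarray(Q, dtype=np.float64))
    K = np.asarray(K, dtype=np.float64)
    if K.shape[0] != h * w or K.shape[1] != Q.shape[1]:
        raise ShapeError(
            f"K shape {K.shape} inconsistent with Q {Q.shape} and map {Z.shape}"
        )
    logits = (Q @ K.T).ravel()
    logits = logits - logits.max()  # stabilised softmax
    weights = np.exp(logits)
    weights /= weights.sum()
    Z_sp = Z * weights.reshape(h, w, 1)
    return Z_sp, weights


def channel_attention(
    Z_prime: np.ndarray,
    V: np.ndarray,
    expand: np.ndarray,
    expand_bias: np.ndarray,
    Z: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Channel gates ``Z'' = sigmoid(conv(Z' V))`` expanded from ``C'`` to
    ``C`` channels, applied multiplicatively over the channels of ``Z``."""
    Z = _check_map(Z)
    h, w, c = Z.shape
    Z_prime = np.asarray(Z_prime, dtype=np.float64).ravel()
    V = np.asarray(V, dtype=np.float64)
    if V.shape[0] != Z_prime.size:
        raise ShapeError(f"V has {V.shape[0]} rows but Z' has {Z_prime.size} entries")
    if expand.shape != (V.shape[1], c):
        raise ShapeError(
            f"channel_expand shape {expand.shape} cannot map C'={V.shape[1]} to C={c}"
        )
    summary = Z_prime @ V  # 1 x C'
    pre = summary @ expand + expand_bias
    gates = 1.0 / (1.0 + np.exp(-pre))
    Z_ch = Z * gates.reshape(1, 1, c)
    return Z_ch, gates


def fuse_head(
    Z_sp: np.ndarray, Z_ch: np.ndarray, w1: float, w2: float
) -> np.ndarray:
    """Trainable-scalar fusion ``Z_gs = w1 * Z_sp + w2 * Z_ch``."""
    Z_sp = np.asarray(Z_sp, dtype=np.float64)
    Z_ch = np.asarray(Z_ch, dtype=np.float64)
    if Z_sp.shape != Z_ch.shape:
        raise ShapeError(f"path shapes differ: {Z_sp.shape} vs {Z_ch.shape}")
    return w1 * Z_sp + w2 * Z_ch


def head_forward(Z: np.ndarray, params: GSAHeadParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One head end to end; returns ``(Z_gs, Z', Z'')``."""
    Q, K, V = project_qkv(Z, params)
    Z_sp, z_prime = spatial_attention(Q, K, Z)
    Z_ch, gates = channel_attention(z_prime, V, params.channel_expand, params.expand_bias, Z)
    return fuse_head(Z_sp, Z_ch, params.w1, params.w2), z_prime, gates


def gsa_forward(
    Z: np.ndarray, heads: Sequence[GSAHeadParams], config: GSAConfig
) -> tuple[np.ndarray, AttentionDiagnostics]:
    """Full multi-head block: per-head fusion, channel concatenation, output
    1x1 convolution back to ``C`` channels.  Output shape equals input shape."""
    Z = _check_map(Z)
    if len(heads) != config.heads:
        raise ConfigError(f"expected {config.heads} heads, got {len(heads)}")
    h, w, c = Z.shape
    if config.output_proj is None:
        raise ConfigError("config.output_proj is not initialised (use init_gsa)")
    if config.output_proj.shape != (len(heads) * c, c):
        raise ShapeError(
            f"output_proj shape {config.output_proj.shape} cannot map "
            f"{len(heads) * c} to {c} channels"
        )
    fused, spatials, gates = [], [], []
    for params in heads:
        Z_gs, z_prime, gate = head_forward(Z, params)
        fused.append(Z_gs)
        spatials.append(z_prime)
        gates.append(gate)
    concat = np.concatenate(fused, axis=2).reshape(h * w, len(heads) * c)
    out = concat @ config.output_proj
    if config.output_bias is not None:
        out = out + config.output_bias
    return out.reshape(h, w, c), AttentionDiagnostics(spatials, gates)


def fusion_scalar_gradients(
    Z: np.ndarray,
    heads: Sequence[GSAHeadParams],
    config: GSAConfig,
    grad_output: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of a scalar loss w.r.t. each head's ``w1``/``w2``.

    ``grad_output`` is dL/dZ_tm with the block's output shape.  The block is
    linear in the fusion scalars, so

        dL/dw1_i = <dL/dZ_tm, conv_out(Z_sp_i placed in head i's slot)>,

    and likewise for ``w2`` with ``Z_ch_i``.  Returns two length-``h`` arrays.
    """
    Z = _check_map(Z)
    h, w, c = Z.shape
    grad_output = np.asarray(grad_output, dtype=np.float64)
    if grad_output.shape != (h, w, c):
        raise ShapeError(
            f"grad_output shape {grad_output.shape} != block output shape {(h, w, c)}"
        )
    grad_flat = grad_output.reshape(h * w, c)
    dw1 = np.zeros(len(heads))
    dw2 = np.zeros(len(heads))
    for i, params in enumerate(heads):
        Q, K, V = project_qkv(Z, params)
        Z_sp, z_prime = spatial_attention(Q, K, Z)
        Z_ch, _ = channel_attention(z_prime, V, params.channel_expand, params.expand_bias, Z)
        w_slice = config.output_proj[i * c : (i + 1) * c, :]
        dw1[i] = np.sum(grad_flat * (Z_sp.reshape(h * w, c) @ w_slice))
        dw2[i] = np.sum(grad_flat * (Z_ch.reshape(h * w, c) @ w_slice))
    return dw1, dw2
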