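"""Extreme learning machine (ELM) multiclass classifier.

A single hidden layer with randomly drawn, fixed weights ``w`` and biases
``b`` maps inputs through an activation ``t``; the output weights ``alpha``
solve the linear system ``H alpha ~ O`` in least squares, where
``H[s, j] = t(x_s . w_j + b_j)`` and ``O`` one-hot encodes the labels.  The
minimum-norm solution is used when ``H`` is rank-deficient.  The number of
hidden nodes must stay below the number of training samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .exceptions import DataError, ParameterError, ShapeError

__all__ = ["ELMModel", "hidden_activations", "fit_elm", "predict_elm", "decision_matrix"]

ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "tanh": np.tanh,
    "relu": lambda z: np.maximum(z, 0.0),
    "identity": lambda z: z,
}


def _resolve_activation(activation) -> tuple[str, Callable]:
    if callable(activation):
        return getattr(activation, "__name__", "custom"), activation
    try:
        return activation, ACTIVATIONS[activation]
    except KeyError:
        raise ParameterError(
            f"unknown activation {activation!r}; choose from {sorted(ACTIVATIONS)}"
        ) from None


@dataclass
class ELMModel:
    """Fitted ELM: fixed hidden layer ``(w, b)``, solved output weights
    ``alpha``, activation name and the ordered class labels."""

    hidden_weights: np.ndarray  # m_features x n_hidden
    biases: np.ndarray  # n_hidden
    output_weights: np.ndarray  # n_hidden x k_classes
    activation: str = "sigmoid"
    class_labels: list = field(default_factory=list)
    seed: int | None = None

    def save(self, path) -> None:
        blob = {
            "hidden_weights": self.hidden_weights.tolist(),
            "biases": self.biases.tolist(),
            "output_weights": self.output_weights.tolist(),
            "activation": self.activation,
            "class_labels": list(self.class_labels),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path) -> "ELMModel":
        blob = json.loads(Path(path).read_text())
        return cls(
            hidden_weights=np.asarray(blob["hidden_weights"], dtype=np.float64),
            biases=np.asarray(blob["biases"], dtype=np.float64),
            output_weights=np.asarray(blob["output_weights"], dtype=np.float64),
            activation=blob["activation"],
            class_labels=blob["class_labels"],
            seed=blob["seed"],
        )


def hidden_activations(X: np.ndarray, w: np.ndarray, b: np.ndarray, activation="sigmoid") -> np.ndarray:
    """Hidden-layer matrix ``H[s, j] = t(x_s . w_j + b_j)``."""
    X = np.asarray(X, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if X.ndim != 2 or w.ndim != 2 or X.shape[1] != w.shape[0]:
        raise ShapeError(f"X {X.shape} and w {w.shape} do not conform")
    if b.shape != (w.shape[1],):
        raise ShapeError(f"bias shape {b.shape} != ({w.shape[1]},)")
    _, fn = _resolve_activation(activation)
    return fn(X @ w + b)


def fit_elm(
    X: np.ndarray,
    y,
    n_hidden: int,
    seed: int = 0,
    activation="sigmoid",
) -> ELMModel:
    """Draw ``w, b ~ Uniform(-1, 1)`` from ``seed`` and solve the output
    weights by minimum-norm least squares against one-hot targets.

    Raises if ``n_hidden`` is not below the sample count (more hidden nodes
    than samples invites interpolation of noise) or if fewer than two classes
    are present.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ShapeError(f"X must be 2-D, got shape {X.shape}")
    n_samples, n_features = X.shape
    if y.shape != (n_samples,):
        raise ShapeError(f"y shape {y.shape} != ({n_samples},)")
    if n_hidden < 1:
        raise ParameterError(f"n_hidden must be >= 1, got {n_hidden}")
    if n_hidden >= n_samples:
        raise ParameterError(
            f"n_hidden ({n_hidden}) must be below the number of samples "
            f"({n_samples}): the hidden layer needs fewer nodes than samples"
        )
    labels = np.unique(y)
    if labels.size < 2:
        raise DataError("need at least two classes to fit a classifier")
    name, _ = _resolve_activation(activation)
    rng = np.random.default_rng(seed)
    w = rng.uniform(-1.0, 1.0, size=(n_features, n_hidden))
    b = rng.uniform(-1.0, 1.0, size=n_hidden)
    H = hidden_activations(X, w, b, activation)
    onehot = (y[:, None] == labels[None, :]).astype(np.float64)
    alpha, *_ = np.linalg.lstsq(H, onehot, rcond=None)
    return ELMModel(
        hidden_weights=w,
        biases=b,
        output_weights=alpha,
        activation=activation,  # callable or name; callables are not serialisable
        class_labels=labels.tolist(),
        seed=seed,
    )


def decision_matrix(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Raw network outputs ``O = H alpha`` (n_samples x k_classes)."""
    H = hidden_activations(X, model.hidden_weights, model.biases, model.activation)
    return H @ model.output_weights


def predict_elm(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Argmax decoding of ``O = H alpha``; ties resolve to the lowest class
    index.  Pure function — the model is not modified."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.hidden_weights.shape[0]:
        raise ShapeError(
            f"X shape {X.shape} does not match model feature dimension "
            f"{model.hidden_weights.shape[0]}"
        )
    scores = decision_matrix(model, X)
    idx = np.argmax(scores, axis=1)  # np.argmax returns the first maximum
    labels = np.asarray(model.class_labels)
    return labels[idx]
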