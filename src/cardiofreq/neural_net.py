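"""From-scratch multilayer perceptron for 3-class window classification.

The classifier is deliberately the simplest thing that fits the task: a
fully connected feed-forward network with logistic-sigmoid units
throughout, a squared-error cost per example

    C_p = 1/2 * sum_t (a_t - b_t)^2

(a = one-hot target, b = output activations), exact backpropagation of
that cost, and plain per-sample gradient descent

    x_{i+1} = x_i - alpha * grad f(x_i)

with a fixed learning rate.  No softmax, momentum, regularization or
early stopping.  The default topology is 8 inputs (band ratios), three
hidden layers of 9 units (27 hidden nodes in total), 3 outputs; class =
argmax of the outputs, ties broken toward the lowest class index
(normal < control < noise).

Everything is seeded: weight initialization and the per-epoch shuffle,
so a training run is bit-for-bit reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from cardiofreq.synthetic_ecg import CLASS_LABELS

DEFAULT_LAYER_SIZES = (8, 9, 9, 9, 3)
DEFAULT_ALPHA = 0.02
DEFAULT_EPOCHS = 45

MODEL_FORMAT_VERSION = 1


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # evaluated piecewise to stay overflow-free for large |z|
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class MlpModel:
    """Layer sizes plus per-layer weight matrices and bias vectors.

    ``weights[l]`` has shape (size_{l+1}, size_l): row i holds the fan-in
    weights of unit i in layer l+1.
    """

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    activation: str = "sigmoid"
    init_seed: int = 0

    @property
    def n_layers(self) -> int:
        return len(self.layer_sizes)

    def copy(self) -> "MlpModel":
        return MlpModel(
            layer_sizes=self.layer_sizes,
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            activation=self.activation,
            init_seed=self.init_seed,
        )

    def save(self, path: str | Path) -> None:
        """Serialize as versioned JSON; round-trips exactly (full float repr)."""
        doc = {
            "format_version": MODEL_FORMAT_VERSION,
            "layer_sizes": list(self.layer_sizes),
            "activation": self.activation,
            "init_seed": self.init_seed,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }
        Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")

    @staticmethod
    def load(path: str | Path) -> "MlpModel":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {doc.get('format_version')!r}")
        return MlpModel(
            layer_sizes=tuple(doc["layer_sizes"]),
            weights=[np.asarray(w, dtype=float) for w in doc["weights"]],
            biases=[np.asarray(b, dtype=float) for b in doc["biases"]],
            activation=doc["activation"],
            init_seed=int(doc["init_seed"]),
        )


@dataclass(frozen=True)
class TrainConfig:
    """Gradient-descent hyperparameters; defaults are the study settings."""

    alpha: float = DEFAULT_ALPHA
    epochs: int = DEFAULT_EPOCHS
    shuffle_seed: int = 0
    update_mode: str = "per_sample"

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.update_mode not in ("per_sample", "batch"):
            raise ValueError(f"update_mode must be per_sample or batch, got {self.update_mode!r}")


@dataclass
class TrainHistory:
    """Per-epoch mean example cost and training accuracy (measured during the pass)."""

    mean_cost: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.mean_cost)


def init_network(layer_sizes: Sequence[int] = DEFAULT_LAYER_SIZES, seed: int = 0) -> MlpModel:
    """Seeded Glorot initialization for logistic-sigmoid units; biases zero.

    Weights are uniform in +-4*sqrt(6/(fan_in+fan_out)), the standard
    scaling for sigmoid activations.  A deep all-sigmoid network trained
    by plain squared-error gradient descent is acutely sensitive to this:
    smaller scales leave the hidden derivatives (at most 1/4 each) so
    attenuated that the net sits on the symmetric cost plateau for far
    more epochs than the study budget allows.
    """
    sizes = tuple(int(s) for s in layer_sizes)
    if len(sizes) < 3:
        raise ValueError("need at least input, one hidden and output layer")
    if any(s < 1 for s in sizes):
        raise ValueError(f"all layer sizes must be >= 1, got {sizes}")
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        bound = 4.0 * np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-bound, bound, size=(fan_out, fan_in)))
        biases.append(np.zeros(fan_out))
    return MlpModel(layer_sizes=sizes, weights=weights, biases=biases, init_seed=seed)


def forward(model: MlpModel, features: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Feed-forward pass; returns (output activations, all layer activations)."""
    x = np.asarray(features, dtype=float)
    if x.shape != (model.layer_sizes[0],):
        raise ValueError(
            f"expected {model.layer_sizes[0]} features, got shape {x.shape}"
        )
    activations = [x]
    for w, b in zip(model.weights, model.biases):
        x = _sigmoid(w @ x + b)
        activations.append(x)
    return x, activations


def cost(target: np.ndarray, output: np.ndarray) -> float:
    """Squared-error cost C_p = 1/2 * sum_t |a_t - b_t|^2."""
    a = np.asarray(target, dtype=float)
    b = np.asarray(output, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"target shape {a.shape} != output shape {b.shape}")
    return 0.5 * float(np.sum((a - b) ** 2))


def backprop_gradients(
    model: MlpModel, features: np.ndarray, target: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Exact gradient of the squared-error cost w.r.t. every weight and bias.

    Chain rule from the output layer back: the output delta is
    (b - a) * b * (1 - b) for sigmoid units under the squared-error cost,
    and each hidden delta is the back-transported delta times the local
    sigmoid derivative.
    """
    grads, _ = _backprop_with_output(model, features, target)
    return grads


def _backprop_with_output(
    model: MlpModel, features: np.ndarray, target: np.ndarray
) -> tuple[tuple[list[np.ndarray], list[np.ndarray]], np.ndarray]:
    a = np.asarray(target, dtype=float)
    if a.shape != (model.layer_sizes[-1],):
        raise ValueError(f"expected {model.layer_sizes[-1]} targets, got shape {a.shape}")
    output, acts = forward(model, features)

    grad_w = [np.empty_like(w) for w in model.weights]
    grad_b = [np.empty_like(b) for b in model.biases]

    delta = (output - a) * output * (1.0 - output)
    for layer in range(len(model.weights) - 1, -1, -1):
        grad_w[layer] = np.outer(delta, acts[layer])
        grad_b[layer] = delta
        if layer > 0:
            h = acts[layer]
            delta = (model.weights[layer].T @ delta) * h * (1.0 - h)
    return (grad_w, grad_b), output


def sgd_update(
    model: MlpModel, gradients: tuple[list[np.ndarray], list[np.ndarray]], alpha: float
) -> MlpModel:
    """In-place gradient-descent step: every parameter -= alpha * gradient."""
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    grad_w, grad_b = gradients
    for w, gw in zip(model.weights, grad_w):
        w -= alpha * gw
    for b, gb in zip(model.biases, grad_b):
        b -= alpha * gb
    return model


def train(
    model: MlpModel,
    features: np.ndarray,
    targets: np.ndarray,
    config: TrainConfig = TrainConfig(),
) -> tuple[MlpModel, TrainHistory]:
    """Train by seeded-shuffle stochastic gradient descent.

    One epoch is one full pass of per-example updates over the training
    set.  The history records each epoch's mean example cost and running
    classification accuracy, both measured on each example *before* its
    update (the usual online training curve).  ``update_mode="batch"``
    instead accumulates the mean gradient over the epoch and applies a
    single step.
    """
    X = np.asarray(features, dtype=float)
    Y = np.asarray(targets, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("need at least one training example")
    if Y.shape != (X.shape[0], model.layer_sizes[-1]):
        raise ValueError(f"targets must have shape ({X.shape[0]}, {model.layer_sizes[-1]})")

    rng = np.random.default_rng(config.shuffle_seed)
    history = TrainHistory()
    n = X.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_cost = 0.0
        n_correct = 0
        if config.update_mode == "per_sample":
            for idx in order:
                grads, out = _backprop_with_output(model, X[idx], Y[idx])
                epoch_cost += cost(Y[idx], out)
                n_correct += int(np.argmax(out) == np.argmax(Y[idx]))
                sgd_update(model, grads, config.alpha)
        else:
            acc_w = [np.zeros_like(w) for w in model.weights]
            acc_b = [np.zeros_like(b) for b in model.biases]
            for idx in order:
                (gw, gb), out = _backprop_with_output(model, X[idx], Y[idx])
                epoch_cost += cost(Y[idx], out)
                n_correct += int(np.argmax(out) == np.argmax(Y[idx]))
                for aw, g in zip(acc_w, gw):
                    aw += g
                for ab, g in zip(acc_b, gb):
                    ab += g
            sgd_update(model, ([g / n for g in acc_w], [g / n for g in acc_b]), config.alpha)
        history.mean_cost.append(epoch_cost / n)
        history.train_accuracy.append(n_correct / n)
    return model, history


def classify(model: MlpModel, features: np.ndarray) -> tuple[str, np.ndarray]:
    """Label = argmax of the output activations; ties go to the lowest class index."""
    output, _ = forward(model, features)
    return CLASS_LABELS[int(np.argmax(output))], output
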