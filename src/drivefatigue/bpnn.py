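"""Multi-layer perceptron trained by backpropagation with momentum and an
adaptive learning rate.

The fatigue classifier is a small fully connected network — by default the
2-6-6-3 topology: two inputs (the ApEn of the steering and yaw windows),
two hidden layers of six tangent-sigmoid units, and three outputs, one per
fatigue level. Training is full-batch gradient descent on the mean squared
error with a momentum term and the classic growth/decay learning-rate
adaptation: a step that inflates the MSE by more than 4 % is rejected and
the rate shrunk; a step that improves it is kept and the rate grown.
Targets are coded +0.9 for the true class and -0.9 elsewhere so the tanh
outputs can actually reach them; decoding is by argmax, so the margin
constant never matters at prediction time.

The network is written from scratch on numpy: the model *is* the method
under study here, not a generic learner, and every formula (forward pass,
backprop gradients, update rule) is visible and unit-testable against
finite differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .signal_io import FatigueLabel

__all__ = ["MLPConfig", "MLPModel", "init_model", "forward", "train",
           "predict", "one_hot_targets", "save_model", "load_model"]

TARGET_HI = 0.9
TARGET_LO = -0.9


@dataclass(frozen=True)
class MLPConfig:
    """Topology and training hyperparameters.

    Defaults follow the fatigue-detection configuration: 2-6-6-3 layers,
    tanh activations, initial learning rate 0.082, momentum 0.95, MSE goal
    1e-4. ``lr_increase``/``lr_decrease``/``max_mse_growth`` parameterise
    the adaptive-rate rule; ``init_scale`` bounds the uniform weight
    initialisation.
    """

    layer_sizes: tuple[int, ...] = (2, 6, 6, 3)
    lr_init: float = 0.082
    momentum: float = 0.95
    mse_goal: float = 1e-4
    max_epochs: int = 20000
    lr_increase: float = 1.05
    lr_decrease: float = 0.7
    max_mse_growth: float = 1.04
    init_scale: float = 0.5
    batch_size: int | None = None  # None = full batch
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.layer_sizes)
        object.__setattr__(self, "layer_sizes", sizes)
        if len(sizes) < 3:
            raise ValueError("need at least input, one hidden and output layer")
        if any(s < 1 for s in sizes):
            raise ValueError("all layer sizes must be >= 1")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if not self.lr_init > 0 or not self.mse_goal > 0:
            raise ValueError("lr_init and mse_goal must be positive")


@dataclass
class MLPModel:
    """Weights, biases and bookkeeping of a trained or initialised network.

    ``weights[l]`` has shape (n_out, n_in) mapping layer l to l+1;
    ``biases[l]`` has length n_out. ``x_mean``/``x_std`` hold the feature
    standardisation constants learned from the training set (identity until
    :func:`train` is called).
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: MLPConfig
    trained_epochs: int = 0
    final_mse: float = float("nan")
    x_mean: np.ndarray | None = None
    x_std: np.ndarray | None = None

    def __post_init__(self) -> None:
        sizes = self.config.layer_sizes
        if len(self.weights) != len(sizes) - 1:
            raise ValueError("one weight matrix per layer transition required")
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (sizes[l + 1], sizes[l]) or b.shape != (sizes[l + 1],):
                raise ValueError(
                    f"layer {l}: expected W{(sizes[l + 1], sizes[l])}, "
                    f"B({sizes[l + 1]},), got W{w.shape}, B{b.shape}"
                )

    def standardize(self, X: np.ndarray) -> np.ndarray:
        if self.x_mean is None:
            return X
        return (X - self.x_mean) / self.x_std


def init_model(config: MLPConfig) -> MLPModel:
    """Initialise weights and biases uniformly on [-init_scale, +init_scale].

    Deterministic for a given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    sizes = config.layer_sizes
    weights, biases = [], []
    for l in range(len(sizes) - 1):
        weights.append(rng.uniform(-config.init_scale, config.init_scale,
                                   size=(sizes[l + 1], sizes[l])))
        biases.append(rng.uniform(-config.init_scale, config.init_scale,
                                  size=sizes[l + 1]))
    return MLPModel(weights=weights, biases=biases, config=config)


def forward(model: MLPModel, x: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
    """Forward pass A = tanh(W . A_prev + B) through every layer.

    ``x`` may be one vector or a (n, d) batch. Returns (activations, output)
    where ``activations`` includes the input as its first element (needed
    for backpropagation); outputs lie strictly inside (-1, 1).
    """
    a = np.atleast_2d(np.asarray(x, dtype=float))
    if a.shape[1] != model.config.layer_sizes[0]:
        raise ValueError(
            f"input dimension {a.shape[1]} != {model.config.layer_sizes[0]}")
    activations = [a]
    for w, b in zip(model.weights, model.biases):
        a = np.tanh(a @ w.T + b)
        activations.append(a)
    return activations, a


def _mse(model: MLPModel, X: np.ndarray, Y: np.ndarray) -> float:
    _, out = forward(model, X)
    return float(np.mean((out - Y) ** 2))


def gradients(
    model: MLPModel, X: np.ndarray, Y: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray], float]:
    """Analytic MSE gradients w.r.t. every weight matrix and bias vector.

    MSE = mean over all samples and output units of (A - Y)^2; returned as
    (dW list, dB list, mse).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    activations, out = forward(model, X)
    n, n_out = out.shape
    mse = float(np.mean((out - Y) ** 2))
    # delta at the output: d(MSE)/d(pre-activation)
    delta = 2.0 * (out - Y) / (n * n_out) * (1.0 - out**2)
    dW: list[np.ndarray] = [None] * len(model.weights)  # type: ignore[list-item]
    dB: list[np.ndarray] = [None] * len(model.biases)  # type: ignore[list-item]
    for l in range(len(model.weights) - 1, -1, -1):
        dW[l] = delta.T @ activations[l]
        dB[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ model.weights[l]) * (1.0 - activations[l] ** 2)
    return dW, dB, mse


class TrainingError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


def one_hot_targets(labels, n_classes: int = 3) -> np.ndarray:
    """Code integer class labels as +/-0.9 target rows for tanh outputs."""
    labels = np.asarray(labels, dtype=int)
    Y = np.full((labels.size, n_classes), TARGET_LO)
    Y[np.arange(labels.size), labels] = TARGET_HI
    return Y


def train(
    model: MLPModel,
    X: np.ndarray,
    Y: np.ndarray,
    standardize: bool = True,
) -> tuple[MLPModel, list[float]]:
    """Train in place by batch gradient descent with momentum and adaptive rate.

    Each epoch applies the momentum update
    ``dW <- momentum * dW_prev - lr * grad`` to every parameter, then
    re-evaluates the MSE: if it grew by more than ``max_mse_growth`` the
    step is rolled back, the momentum memory cleared and
    ``lr <- lr * lr_decrease``; otherwise the step stands and, on an
    improvement, ``lr <- lr * lr_increase``. Stops at ``mse_goal`` or
    ``max_epochs``. Returns (model, accepted-epoch MSE trace); the trace
    starts with the pre-training MSE.
    """
    cfg = model.config
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] != Y.shape[0] or X.shape[0] < 1:
        raise ValueError("X and Y must be non-empty and aligned")

    if standardize:
        model.x_mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0
        model.x_std = std
    Xs = model.standardize(X)

    rng = np.random.default_rng(cfg.seed + 1)
    lr = cfg.lr_init
    vel_w = [np.zeros_like(w) for w in model.weights]
    vel_b = [np.zeros_like(b) for b in model.biases]
    mse = _mse(model, Xs, Y)
    trace = [mse]
    epoch = 0
    for epoch in range(1, cfg.max_epochs + 1):
        if cfg.batch_size is None or cfg.batch_size >= Xs.shape[0]:
            Xb, Yb = Xs, Y
        else:
            idx = rng.choice(Xs.shape[0], size=cfg.batch_size, replace=False)
            Xb, Yb = Xs[idx], Y[idx]
        dW, dB, batch_mse = gradients(model, Xb, Yb)
        if not np.isfinite(batch_mse):
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        prev_w = [w.copy() for w in model.weights]
        prev_b = [b.copy() for b in model.biases]
        for l in range(len(model.weights)):
            vel_w[l] = cfg.momentum * vel_w[l] - lr * dW[l]
            vel_b[l] = cfg.momentum * vel_b[l] - lr * dB[l]
            model.weights[l] += vel_w[l]
            model.biases[l] += vel_b[l]
        new_mse = _mse(model, Xs, Y)
        if not np.isfinite(new_mse):
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        if new_mse > cfg.max_mse_growth * mse:
            # reject: roll back parameters, clear momentum, shrink the rate
            model.weights = prev_w
            model.biases = prev_b
            vel_w = [np.zeros_like(w) for w in model.weights]
            vel_b = [np.zeros_like(b) for b in model.biases]
            lr *= cfg.lr_decrease
        else:
            if new_mse < mse:
                lr *= cfg.lr_increase
            mse = new_mse
            trace.append(mse)
        if mse <= cfg.mse_goal:
            break
    model.trained_epochs = epoch
    model.final_mse = mse
    return model, trace


def predict(model: MLPModel, x: np.ndarray) -> tuple[FatigueLabel, np.ndarray]:
    """Classify one feature vector; ties break toward the lower level index.

    Returns (label, raw 3-vector of network outputs). Input standardisation
    learned at training time is applied automatically.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    _, out = forward(model, model.standardize(x))
    return FatigueLabel(int(np.argmax(out[0]))), out[0]


def predict_batch(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Vectorised argmax classification of a feature matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    _, out = forward(model, model.standardize(X))
    return np.argmax(out, axis=1)


def save_model(model: MLPModel, path) -> None:
    """Serialise the model to JSON; floats round-trip bit-exactly."""
    payload = {
        "config": asdict(model.config),
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "trained_epochs": model.trained_epochs,
        "final_mse": model.final_mse,
        "x_mean": None if model.x_mean is None else model.x_mean.tolist(),
        "x_std": None if model.x_std is None else model.x_std.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> MLPModel:
    with open(path) as fh:
        payload = json.load(fh)
    cfg_dict = payload["config"]
    cfg_dict["layer_sizes"] = tuple(cfg_dict["layer_sizes"])
    cfg = MLPConfig(**cfg_dict)
    model = MLPModel(
        weights=[np.asarray(w, dtype=float) for w in payload["weights"]],
        biases=[np.asarray(b, dtype=float) for b in payload["biases"]],
        config=cfg,
        trained_epochs=payload["trained_epochs"],
        final_mse=payload["final_mse"],
    )
    if payload["x_mean"] is not None:
        model.x_mean = np.asarray(payload["x_mean"], dtype=float)
        model.x_std = np.asarray(payload["x_std"], dtype=float)
    return model
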