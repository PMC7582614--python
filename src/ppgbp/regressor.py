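"""Fully connected SBP/DBP regressor.

The predictor maps one cycle's selected feature vector (32 inputs by
default) through fully connected hidden layers of widths 2048/4096/8192/2048
with ReLU activations to a 2-dimensional linear output (SBP, DBP) in mmHg.
Every layer computes ``O = act(W I + b)``; the output layer uses the
identity activation.

Training minimizes mean squared error over the two outputs with the Nadam
optimizer (Adam with Nesterov momentum) on shuffled mini-batches (512 rows
by default), monitoring RMSE and reporting MAE per epoch, with early
stopping on validation RMSE.  Inputs and targets are z-scored internally
using statistics of the training split; predictions are returned in mmHg.
Target scaling matters: without it an Adam-family optimizer at a
conventional learning rate cannot move the output layer to the ~100 mmHg
operating point in any reasonable epoch budget.

The hidden widths are configurable so that desk-scale experiments and tests
can use small networks; the wide architecture is the default for full runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "RegressorConfig",
    "TrainedRegressor",
    "split_dataset",
    "initialize_network",
    "forward",
    "train",
    "predict",
    "save_model",
    "load_model",
]


@dataclass
class RegressorConfig:
    input_dim: int = 32
    hidden_widths: tuple[int, ...] = (2048, 4096, 8192, 2048)
    output_dim: int = 2
    activation: str = "relu"
    batch_size: int = 512
    optimizer: str = "nadam"
    learning_rate: float = 2e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    max_epochs: int = 500
    patience: int = 10
    split_fractions: tuple[float, float, float] = (0.70, 0.20, 0.10)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.hidden_widths):
            raise ValueError("hidden widths must be positive")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.activation != "relu":
            raise ValueError("only the ReLU activation is supported")
        if self.optimizer != "nadam":
            raise ValueError("only the Nadam optimizer is supported")


def split_dataset(
    features: np.ndarray,
    labels: np.ndarray,
    fractions: tuple[float, float, float] = (0.70, 0.20, 0.10),
    seed: int = 0,
) -> tuple[tuple[np.ndarray, np.ndarray], ...]:
    """Shuffle rows and split into (train, test, validation) subsets.

    Subset sizes are ``round(f * n)`` for the first two fractions with the
    remainder going to validation, so each size is within one row of
    ``f * n`` and the subsets are disjoint and exhaustive.
    """
    x = np.asarray(features)
    y = np.asarray(labels)
    n = len(x)
    if len(y) != n:
        raise ValueError("features and labels disagree in length")
    if n < 10:
        raise ValueError("need at least 10 rows to split")
    if abs(sum(fractions) - 1.0) > 1e-9 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_test = int(round(fractions[1] * n))
    n_test = min(n_test, n - n_train)
    i_tr, i_te, i_va = (
        perm[:n_train],
        perm[n_train : n_train + n_test],
        perm[n_train + n_test :],
    )
    return (x[i_tr], y[i_tr]), (x[i_te], y[i_te]), (x[i_va], y[i_va])


def initialize_network(
    config: RegressorConfig, rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """He-initialized weights and zero biases for the configured layer stack."""
    dims = [config.input_dim, *config.hidden_widths, config.output_dim]
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def forward(
    weights: list[np.ndarray],
    biases: list[np.ndarray],
    x: np.ndarray,
) -> np.ndarray:
    """Pure network evaluation: affine + ReLU per hidden layer, linear output.

    ``x`` may be a single row or a matrix; no input/output scaling is
    applied here.
    """
    a = np.atleast_2d(np.asarray(x, dtype=float))
    if a.shape[1] != weights[0].shape[0]:
        raise ValueError(
            f"input width {a.shape[1]} != network input dim {weights[0].shape[0]}"
        )
    for w, b in zip(weights[:-1], biases[:-1]):
        a = np.maximum(a @ w + b, 0.0)
    out = a @ weights[-1] + biases[-1]
    return out if np.asarray(x).ndim > 1 else out[0]


@dataclass
class TrainedRegressor:
    """Network weights plus the fit-time scalers and training history."""

    config: RegressorConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    y_sd: np.ndarray
    history: pd.DataFrame

    def predict(self, features: np.ndarray) -> np.ndarray:
        return predict(self, features)


class _Nadam:
    """Adam with Nesterov momentum (Dozat), one state pair per parameter."""

    def __init__(self, params: list[np.ndarray], cfg: RegressorConfig):
        self.lr, self.b1, self.b2, self.eps = (
            cfg.learning_rate,
            cfg.beta1,
            cfg.beta2,
            cfg.epsilon,
        )
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, t = self.b1, self.b2, self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = b1 * m / (1 - b1 ** (t + 1)) + (1 - b1) * g / (1 - b1**t)
            v_hat = v / (1 - b2**t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _errors(
    weights, biases, x_std, y_true_mmHg, y_mean, y_sd
) -> tuple[float, float]:
    pred = forward(weights, biases, x_std) * y_sd + y_mean
    err = pred - y_true_mmHg
    return float(np.sqrt(np.mean(err**2))), float(np.mean(np.abs(err)))


def train(
    config: RegressorConfig,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> TrainedRegressor:
    """Mini-batch Nadam training on MSE with early stopping.

    History records per-epoch train (and validation, when given) RMSE and
    MAE in mmHg.  The weights with the best validation RMSE are retained;
    without a validation set the final weights are kept.  ``max_epochs = 0``
    returns the freshly initialized network unchanged.

    Raises
    ------
    RuntimeError
        If the loss becomes non-finite during training.
    """
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if x_train.shape[1] != config.input_dim:
        raise ValueError("x_train width does not match config.input_dim")
    if y_train.ndim != 2 or y_train.shape[1] != config.output_dim:
        raise ValueError("y_train must be (n, output_dim)")
    rng = np.random.default_rng(config.seed)

    x_mean, x_sd = x_train.mean(axis=0), x_train.std(axis=0)
    x_sd = np.where(x_sd == 0, 1.0, x_sd)
    y_mean, y_sd = y_train.mean(axis=0), y_train.std(axis=0)
    y_sd = np.where(y_sd == 0, 1.0, y_sd)
    xs = (x_train - x_mean) / x_sd
    ys = (y_train - y_mean) / y_sd
    has_val = x_val is not None and y_val is not None and len(x_val) > 0
    if has_val:
        xs_val = (np.asarray(x_val, dtype=float) - x_mean) / x_sd
        y_val = np.asarray(y_val, dtype=float)

    weights, biases = initialize_network(config, rng)
    params = weights + biases
    opt = _Nadam(params, config)

    n = len(xs)
    best_val = np.inf
    best_snapshot = ([w.copy() for w in weights], [b.copy() for b in biases])
    stall = 0
    records = []
    for epoch in range(config.max_epochs):
        perm = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            xb, yb = xs[idx], ys[idx]
            # forward with cached activations
            acts = [xb]
            a = xb
            for w, b in zip(weights[:-1], biases[:-1]):
                a = np.maximum(a @ w + b, 0.0)
                acts.append(a)
            out = a @ weights[-1] + biases[-1]
            delta = 2.0 * (out - yb) / (len(idx) * config.output_dim)
            if not np.isfinite(delta).all():
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}; "
                    "reduce the learning rate or check the inputs"
                )
            grads_w = [None] * len(weights)
            grads_b = [None] * len(biases)
            for layer in range(len(weights) - 1, -1, -1):
                grads_w[layer] = acts[layer].T @ delta
                grads_b[layer] = delta.sum(axis=0)
                if layer > 0:
                    delta = (delta @ weights[layer].T) * (acts[layer] > 0)
            opt.step(params, grads_w + grads_b)

        tr_rmse, tr_mae = _errors(weights, biases, xs, y_train, y_mean, y_sd)
        row = {"epoch": epoch, "train_rmse": tr_rmse, "train_mae": tr_mae}
        if has_val:
            va_rmse, va_mae = _errors(weights, biases, xs_val, y_val, y_mean, y_sd)
            row.update(val_rmse=va_rmse, val_mae=va_mae)
            if va_rmse < best_val - 1e-12:
                best_val = va_rmse
                best_snapshot = (
                    [w.copy() for w in weights],
                    [b.copy() for b in biases],
                )
                stall = 0
            else:
                stall += 1
        records.append(row)
        if has_val and stall > config.patience:
            break

    if has_val and np.isfinite(best_val):
        weights, biases = best_snapshot
    return TrainedRegressor(
        config=config,
        weights=weights,
        biases=biases,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
        history=pd.DataFrame(records),
    )


def predict(model: TrainedRegressor, features: np.ndarray) -> np.ndarray:
    """Per-row (SBP, DBP) predictions in mmHg.

    Applies the fit-time feature standardization, evaluates the network,
    and un-scales the outputs.  Accepts a single row or a matrix; row order
    is preserved.
    """
    x = np.asarray(features, dtype=float)
    single = x.ndim == 1
    x2 = np.atleast_2d(x)
    if x2.shape[1] != model.config.input_dim:
        raise ValueError("feature width does not match the trained model")
    xs = (x2 - model.x_mean) / model.x_sd
    out = forward(model.weights, model.biases, xs) * model.y_sd + model.y_mean
    return out[0] if single else out


def save_model(model: TrainedRegressor, path) -> None:
    """Persist a trained model as a flat .npz container."""
    payload = {
        "config_json": np.bytes_(json.dumps(asdict(model.config))),
        "n_layers": np.array(len(model.weights)),
        "x_mean": model.x_mean,
        "x_sd": model.x_sd,
        "y_mean": model.y_mean,
        "y_sd": model.y_sd,
    }
    for i, (w, b) in enumerate(zip(model.weights, model.biases)):
        payload[f"w{i}"] = w
        payload[f"b{i}"] = b
    np.savez(path, **payload)


def load_model(path) -> TrainedRegressor:
    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["config_json"]).decode())
        for key in ("hidden_widths", "split_fractions"):
            cfg_dict[key] = tuple(cfg_dict[key])
        config = RegressorConfig(**cfg_dict)
        n_layers = int(data["n_layers"])
        weights = [data[f"w{i}"] for i in range(n_layers)]
        biases = [data[f"b{i}"] for i in range(n_layers)]
        return TrainedRegressor(
            config=config,
            weights=weights,
            biases=biases,
            x_mean=data["x_mean"],
            x_sd=data["x_sd"],
            y_mean=data["y_mean"],
            y_sd=data["y_sd"],
            history=pd.DataFrame(),
        )
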