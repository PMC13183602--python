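"""Feed-forward surrogate networks for the mechanistic cell model.

The surrogate is a small multilayer perceptron (default 4-16-16-4, ReLU
hidden activations, dropout 0.1 during training) trained by Adam on
standardized inputs and outputs with an 80:20 train-test split and early
stopping on the test loss.  Two directions are supported:

``forward``
    transport parameters (fractions of baseline) -> cytosolic [Na+], [K+],
    Va, Vb.
``inverse``
    observables (cytosolic [Na+], [K+], transcellular Na+ and K+ fluxes)
    -> the four transport parameters.

The implementation is a plain numpy MLP so that trained bundles are fully
portable: a JSON manifest plus a CSV weight table round-trips exactly.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from episurf.cellmodel import ConfigurationError
from episurf.datagen import Dataset

__all__ = [
    "MLPSpec",
    "Scaler",
    "TrainConfig",
    "TrainedSurrogate",
    "direction_columns",
    "mlp_forward",
    "train_surrogate",
    "predict",
    "save_surrogate",
    "load_surrogate",
]

FORWARD_TARGETS = ("Na_cell", "K_cell", "Va", "Vb")
INVERSE_FEATURES = ("Na_cell", "K_cell", "J_Na_trans", "J_K_trans")


@dataclass(frozen=True)
class MLPSpec:
    layer_sizes: tuple[int, ...] = (4, 16, 16, 4)
    dropout_rate: float = 0.1

    def __post_init__(self):
        if len(self.layer_sizes) < 3:
            raise ConfigurationError("need at least one hidden layer")
        if not (0 <= self.dropout_rate < 1):
            raise ConfigurationError("dropout rate must lie in [0, 1)")


@dataclass(frozen=True)
class Scaler:
    """Per-column standardization statistics (training-split only)."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Scaler":
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        if np.any(sd <= 0):
            bad = [int(i) for i in np.flatnonzero(sd <= 0)]
            raise ConfigurationError(f"constant column(s) {bad}: cannot scale")
        return cls(mean=mean, sd=sd)

    def transform(self, X):
        return (X - self.mean) / self.sd

    def inverse(self, Z):
        return Z * self.sd + self.mean


@dataclass(frozen=True)
class TrainConfig:
    split_fraction: float = 0.8
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 2000
    patience: int = 100
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.split_fraction < 1):
            raise ConfigurationError("split_fraction must lie in (0, 1)")


@dataclass
class TrainedSurrogate:
    spec: MLPSpec
    weights: list[np.ndarray]         # W per layer, shape (n_in, n_out)
    biases: list[np.ndarray]
    x_scaler: Scaler
    y_scaler: Scaler
    direction: str                    # "forward" | "inverse"
    feature_names: tuple[str, ...]
    target_names: tuple[str, ...]
    history: dict = field(default_factory=dict)
    feature_range: tuple[np.ndarray, np.ndarray] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        sizes = self.spec.layer_sizes
        for k, (W, b) in enumerate(zip(self.weights, self.biases)):
            if W.shape != (sizes[k], sizes[k + 1]) or b.shape != (sizes[k + 1],):
                raise ConfigurationError(
                    f"layer {k} weight shape {W.shape} inconsistent with "
                    f"spec {sizes}")


def direction_columns(direction: str,
                      param_names: Sequence[str]) -> tuple[tuple, tuple]:
    """(feature, target) column names for a training direction."""
    params = tuple(f"frac_{p}" for p in param_names)
    if direction == "forward":
        return params, FORWARD_TARGETS
    if direction == "inverse":
        return INVERSE_FEATURES, params
    raise ConfigurationError(f"unknown direction {direction!r}")


# --------------------------------------------------------------------------
# Network evaluation
# --------------------------------------------------------------------------

def _net_forward(weights, biases, Z, dropout_rate=0.0, rng=None):
    """Standardized-space forward pass; returns activations per layer.

    Dropout (inverted scaling) is applied to hidden activations only when a
    generator is supplied.
    """
    acts = [Z]
    h = Z
    last = len(weights) - 1
    for k, (W, b) in enumerate(zip(weights, biases)):
        h = h @ W + b
        if k < last:
            h = np.maximum(h, 0.0)
            if rng is not None and dropout_rate > 0.0:
                mask = (rng.random(h.shape) >= dropout_rate)
                h = h * mask / (1.0 - dropout_rate)
        acts.append(h)
    return acts


def mlp_forward(surrogate: TrainedSurrogate, x, training_mode: bool = False,
                dropout_seed: int | None = None) -> np.ndarray:
    """Full surrogate evaluation: input scaler -> network -> output scaler.

    Inference (``training_mode=False``) is deterministic; dropout masks are
    drawn only in training mode, seeded by ``dropout_seed``.
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    n_in = surrogate.spec.layer_sizes[0]
    if X.shape[1] != n_in:
        raise ConfigurationError(
            f"feature dimension {X.shape[1]} does not match spec {n_in}")
    Z = surrogate.x_scaler.transform(X)
    rng = None
    if training_mode and surrogate.spec.dropout_rate > 0:
        rng = np.random.default_rng(dropout_seed)
    acts = _net_forward(surrogate.weights, surrogate.biases, Z,
                        surrogate.spec.dropout_rate, rng)
    return surrogate.y_scaler.inverse(acts[-1])


def predict(surrogate: TrainedSurrogate, data) -> pd.DataFrame:
    """Vectorized prediction with named columns.

    ``data`` may be a DataFrame containing the surrogate's feature columns
    or a plain array in feature order.  Inputs outside the training feature
    range trigger a warning (extrapolation is supported but less accurate),
    never a failure.
    """
    if isinstance(data, pd.DataFrame):
        missing = [c for c in surrogate.feature_names if c not in data.columns]
        if missing:
            raise ConfigurationError(
                f"missing feature column(s): {', '.join(missing)}")
        X = data.loc[:, list(surrogate.feature_names)].to_numpy(dtype=float)
        index = data.index
    else:
        X = np.atleast_2d(np.asarray(data, dtype=float))
        index = None
    if surrogate.feature_range is not None:
        lo, hi = surrogate.feature_range
        tol = 1e-9 * (np.abs(hi) + 1.0)
        if np.any(X < lo - tol) or np.any(X > hi + tol):
            warnings.warn("input outside the training feature range; "
                          "surrogate is extrapolating", stacklevel=2)
    Y = mlp_forward(surrogate, X, training_mode=False)
    return pd.DataFrame(Y, columns=list(surrogate.target_names), index=index)


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------

def _init_params(sizes, rng):
    weights, biases = [], []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.normal(0.0, math.sqrt(2.0 / n_in), (n_in, n_out)))
        biases.append(np.zeros(n_out))
    return weights, biases


def _backward(weights, acts, pre_relu_masks, delta_out):
    """Gradients of the batch-mean squared error wrt weights and biases."""
    gW = [None] * len(weights)
    gb = [None] * len(weights)
    delta = delta_out
    for k in range(len(weights) - 1, -1, -1):
        gW[k] = acts[k].T @ delta
        gb[k] = delta.sum(axis=0)
        if k > 0:
            delta = (delta @ weights[k].T) * pre_relu_masks[k - 1]
    return gW, gb


def _loss(weights, biases, Z, T):
    pred = _net_forward(weights, biases, Z)[-1]
    return float(np.mean((pred - T) ** 2))


def _assemble(datasets, direction):
    if isinstance(datasets, Dataset):
        datasets = [datasets]
    params = None
    frames = []
    meta = []
    for ds in datasets:
        p = tuple(ds.metadata["design"]["param_names"])
        if params is None:
            params = p
        elif set(p) != set(params):
            raise ConfigurationError("datasets vary different parameters")
        ds.require_complete()
        frames.append(ds.table)
        meta.append({k: ds.metadata.get(k) for k in
                     ("variant", "seed", "n_rows")})
    table = pd.concat(frames, ignore_index=True)
    features, targets = direction_columns(direction, params)
    missing = [c for c in (*features, *targets) if c not in table.columns]
    if missing:
        raise ConfigurationError(f"dataset lacks column(s): {', '.join(missing)}")
    X = table.loc[:, list(features)].to_numpy(dtype=float)
    Y = table.loc[:, list(targets)].to_numpy(dtype=float)
    return X, Y, features, targets, meta


def train_surrogate(datasets, direction: str,
                    config: TrainConfig | None = None,
                    spec: MLPSpec | None = None) -> TrainedSurrogate:
    """Train a surrogate on one dataset or a merged list of datasets.

    The split, initialization, batch order and dropout masks are all driven
    by a single seeded generator, so identical configurations reproduce
    identical weights bit for bit.  Early stopping restores the weights of
    the best test-loss epoch.
    """
    config = config or TrainConfig()
    X, Y, features, targets, meta = _assemble(datasets, direction)
    n = len(X)
    if n < 50:
        raise ConfigurationError(f"refusing to train on {n} rows (< 50)")
    if spec is None:
        spec = MLPSpec(layer_sizes=(X.shape[1], 16, 16, Y.shape[1]))

    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    n_train = int(round(config.split_fraction * n))
    tr, te = perm[:n_train], perm[n_train:]
    x_scaler = Scaler.fit(X[tr])
    y_scaler = Scaler.fit(Y[tr])
    Ztr, Ttr = x_scaler.transform(X[tr]), y_scaler.transform(Y[tr])
    Zte, Tte = x_scaler.transform(X[te]), y_scaler.transform(Y[te])

    weights, biases = _init_params(spec.layer_sizes, rng)
    mW = [np.zeros_like(W) for W in weights]
    vW = [np.zeros_like(W) for W in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]
    b1, b2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    t_adam = 0

    train_hist, test_hist = [], []
    best_loss = math.inf
    best_epoch = -1
    best = None
    since_best = 0
    drop = spec.dropout_rate
    last = len(weights) - 1

    for epoch in range(config.max_epochs):
        order = rng.permutation(n_train)
        for start in range(0, n_train, config.batch_size):
            idx = order[start:start + config.batch_size]
            Zb, Tb = Ztr[idx], Ttr[idx]
            # forward with dropout, retaining masks for backprop
            acts = [Zb]
            masks = []
            h = Zb
            for k, (W, b) in enumerate(zip(weights, biases)):
                h = h @ W + b
                if k < last:
                    relu = h > 0
                    h = h * relu
                    if drop > 0:
                        dmask = (rng.random(h.shape) >= drop) / (1.0 - drop)
                        h = h * dmask
                        masks.append(relu * dmask)
                    else:
                        masks.append(relu.astype(float))
                acts.append(h)
            delta = 2.0 * (acts[-1] - Tb) / (len(idx) * h.shape[1])
            gW, gb = _backward(weights, acts, masks, delta)
            t_adam += 1
            c1 = 1 - b1 ** t_adam
            c2 = 1 - b2 ** t_adam
            for k in range(len(weights)):
                mW[k] = b1 * mW[k] + (1 - b1) * gW[k]
                vW[k] = b2 * vW[k] + (1 - b2) * gW[k] ** 2
                weights[k] -= lr * (mW[k] / c1) / (np.sqrt(vW[k] / c2) + eps)
                mb[k] = b1 * mb[k] + (1 - b1) * gb[k]
                vb[k] = b2 * vb[k] + (1 - b2) * gb[k] ** 2
                biases[k] -= lr * (mb[k] / c1) / (np.sqrt(vb[k] / c2) + eps)

        tr_loss = _loss(weights, biases, Ztr, Ttr)
        te_loss = _loss(weights, biases, Zte, Tte)
        if not (math.isfinite(tr_loss) and math.isfinite(te_loss)):
            raise ConfigurationError(
                f"non-finite loss at epoch {epoch} (train {tr_loss}, "
                f"test {te_loss}); lower the learning rate")
        train_hist.append(tr_loss)
        test_hist.append(te_loss)
        if te_loss < best_loss:
            best_loss = te_loss
            best_epoch = epoch
            best = ([W.copy() for W in weights], [b.copy() for b in biases])
            since_best = 0
        else:
            since_best += 1
            if since_best > config.patience:
                break

    weights, biases = best
    history = {"train_loss": train_hist, "test_loss": test_hist,
               "best_epoch": best_epoch, "best_test_loss": best_loss}
    return TrainedSurrogate(
        spec=spec, weights=weights, biases=biases,
        x_scaler=x_scaler, y_scaler=y_scaler, direction=direction,
        feature_names=features, target_names=targets, history=history,
        feature_range=(X.min(axis=0), X.max(axis=0)),
        provenance={"config": {"split_fraction": config.split_fraction,
                               "learning_rate": config.learning_rate,
                               "batch_size": config.batch_size,
                               "max_epochs": config.max_epochs,
                               "patience": config.patience,
                               "seed": config.seed},
                    "datasets": meta, "n_samples": int(n)})


# --------------------------------------------------------------------------
# Serialization: directory with manifest.json + weights.csv
# --------------------------------------------------------------------------

def save_surrogate(surrogate: TrainedSurrogate, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "spec": {"layer_sizes": list(surrogate.spec.layer_sizes),
                 "dropout_rate": surrogate.spec.dropout_rate},
        "direction": surrogate.direction,
        "feature_names": list(surrogate.feature_names),
        "target_names": list(surrogate.target_names),
        "x_scaler": {"mean": surrogate.x_scaler.mean.tolist(),
                     "sd": surrogate.x_scaler.sd.tolist()},
        "y_scaler": {"mean": surrogate.y_scaler.mean.tolist(),
                     "sd": surrogate.y_scaler.sd.tolist()},
        "history": surrogate.history,
        "provenance": surrogate.provenance,
    }
    if surrogate.feature_range is not None:
        manifest["feature_range"] = {
            "lo": surrogate.feature_range[0].tolist(),
            "hi": surrogate.feature_range[1].tolist()}
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    rows = []
    for k, (W, b) in enumerate(zip(surrogate.weights, surrogate.biases)):
        for i in range(W.shape[0]):
            for j in range(W.shape[1]):
                rows.append((k, "W", i, j, W[i, j]))
        for j in range(b.shape[0]):
            rows.append((k, "b", 0, j, b[j]))
    df = pd.DataFrame(rows, columns=["layer", "kind", "i", "j", "value"])
    df.to_csv(path / "weights.csv", index=False, float_format="%.17g")


def load_surrogate(path: str | Path) -> TrainedSurrogate:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    spec = MLPSpec(layer_sizes=tuple(manifest["spec"]["layer_sizes"]),
                   dropout_rate=float(manifest["spec"]["dropout_rate"]))
    sizes = spec.layer_sizes
    weights = [np.zeros((sizes[k], sizes[k + 1])) for k in range(len(sizes) - 1)]
    biases = [np.zeros(sizes[k + 1]) for k in range(len(sizes) - 1)]
    df = pd.read_csv(path / "weights.csv", float_precision="round_trip")
    for layer, kind, i, j, value in df.itertuples(index=False):
        try:
            if kind == "W":
                weights[layer][i, j] = value
            else:
                biases[layer][j] = value
        except IndexError:
            raise ConfigurationError(
                f"weight entry (layer {layer}, {kind}[{i},{j}]) outside the "
                f"manifest layer sizes {sizes}") from None
    fr = None
    if "feature_range" in manifest:
        fr = (np.asarray(manifest["feature_range"]["lo"], dtype=float),
              np.asarray(manifest["feature_range"]["hi"], dtype=float))
    return TrainedSurrogate(
        spec=spec, weights=weights, biases=biases,
        x_scaler=Scaler(np.asarray(manifest["x_scaler"]["mean"], dtype=float),
                        np.asarray(manifest["x_scaler"]["sd"], dtype=float)),
        y_scaler=Scaler(np.asarray(manifest["y_scaler"]["mean"], dtype=float),
                        np.asarray(manifest["y_scaler"]["sd"], dtype=float)),
        direction=manifest["direction"],
        feature_names=tuple(manifest["feature_names"]),
        target_names=tuple(manifest["target_names"]),
        history=manifest.get("history", {}),
        feature_range=fr,
        provenance=manifest.get("provenance", {}))
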