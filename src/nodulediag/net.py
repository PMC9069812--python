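"""Encoder-mean-pooling network for mixed tabular features, in plain numpy.

Architecture: every input feature i (a one-hot block or a z-normalized
continuous vector, dimension dim_i) passes through its own dense encoder
``Encoder_i: dim_i -> 32``; the n encoded vectors are averaged element-wise
(mean pooling) into a single 32-vector h; two further dense layers map
h -> 32 -> 1 to the scalar confidence score y.  Every dense layer computes
``tanh(x W + b)``, including the output layer, so y lies in (-1, 1) and a
large y means high confidence of malignancy.

Training is plain mini-batch gradient descent on squared error against
labels coded -1 (benign) / +1 (malignant); a sigmoid/cross-entropy head is
selectable.  Gradients come from hand-written reverse-mode backpropagation
through the pooling and all dense layers; they are validated against
central finite differences in the test suite.  The network is small enough
that no deep-learning framework is needed or used.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during training."""


@dataclass
class DenseLayerParams:
    """Weights (in_dim, out_dim) and bias (out_dim) of one dense layer."""

    W: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.W.ndim != 2 or self.b.ndim != 1 or self.W.shape[1] != self.b.shape[0]:
            raise ValueError(f"inconsistent dense shapes {self.W.shape}, {self.b.shape}")
        if not (np.isfinite(self.W).all() and np.isfinite(self.b).all()):
            raise ValueError("dense parameters must be finite")


@dataclass
class NetworkParams:
    """All parameters: one encoder per feature plus the two hidden layers."""

    encoders: list[DenseLayerParams]
    hidden1: DenseLayerParams
    hidden2: DenseLayerParams

    @property
    def hidden_dim(self) -> int:
        return self.hidden1.W.shape[0]

    def copy(self) -> "NetworkParams":
        return copy.deepcopy(self)


@dataclass
class TrainConfig:
    """Hyperparameters of the gradient-descent trainer (all configurable;
    the architecture itself fixes only the layer dimensions)."""

    learning_rate: float = 0.01
    epochs: int = 200
    batch_size: int = 32
    init_scale: float | None = None  # default 1/sqrt(in_dim) per layer
    seed: int = 0
    val_fraction: float = 0.15
    loss: str = "mse"  # "mse" (tanh head, labels +-1) or "bce" (sigmoid head)
    hidden_dim: int = 32

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("learning rate, epochs and batch size must be positive")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.loss not in ("mse", "bce"):
            raise ValueError(f"unknown loss {self.loss!r}")


def _init_dense(in_dim: int, out_dim: int, rng: np.random.Generator,
                scale: float | None) -> DenseLayerParams:
    s = scale if scale is not None else 1.0 / math.sqrt(in_dim)
    return DenseLayerParams(
        W=rng.uniform(-s, s, size=(in_dim, out_dim)),
        b=rng.uniform(-s, s, size=out_dim),
    )


def init_params(feature_dims: Sequence[int], hidden_dim: int = 32,
                seed: int = 0, init_scale: float | None = None) -> NetworkParams:
    """Seeded small-uniform initialization for the given feature dimensions."""
    rng = np.random.default_rng(seed)
    encoders = [_init_dense(d, hidden_dim, rng, init_scale) for d in feature_dims]
    return NetworkParams(
        encoders=encoders,
        hidden1=_init_dense(hidden_dim, hidden_dim, rng, init_scale),
        hidden2=_init_dense(hidden_dim, 1, rng, init_scale),
    )


def dense_forward(x: np.ndarray, layer: DenseLayerParams) -> np.ndarray:
    """tanh(x W + b); x may be a single vector or a batch (rows)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != layer.W.shape[0]:
        raise ValueError(f"input dim {x.shape[-1]} != layer in_dim {layer.W.shape[0]}")
    return np.tanh(x @ layer.W + layer.b)


def _sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


def _forward_cache(features: Sequence[np.ndarray], params: NetworkParams,
                   loss: str = "mse"):
    """Batch forward pass keeping intermediates for backprop."""
    if len(features) != len(params.encoders):
        raise ValueError(
            f"{len(features)} features but {len(params.encoders)} encoders")
    H = []
    for i, (x, enc) in enumerate(zip(features, params.encoders)):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != enc.W.shape[0]:
            raise ValueError(f"feature {i}: dim {x.shape[1]} != encoder "
                             f"in_dim {enc.W.shape[0]}")
        H.append(np.tanh(x @ enc.W + enc.b))
    h = np.mean(H, axis=0)                       # (B, hidden_dim)
    H1 = np.tanh(h @ params.hidden1.W + params.hidden1.b)
    A2 = H1 @ params.hidden2.W + params.hidden2.b  # (B, 1)
    y = _sigmoid(A2) if loss == "bce" else np.tanh(A2)
    return y[:, 0], {"X": [np.atleast_2d(np.asarray(x, float)) for x in features],
                     "H": H, "h": h, "H1": H1, "y": y}


def forward(features: Sequence[np.ndarray], params: NetworkParams
            ) -> tuple[np.ndarray, dict]:
    """Confidence scores y in (-1, 1) plus the hidden state.

    ``features`` is one array per input feature; single patients (1-d
    arrays) and batches (2-d arrays) are both accepted.  The returned dict
    holds the per-feature hidden vectors (``hidden_features``) and the
    pooled vector ``h``.
    """
    y, cache = _forward_cache(features, params)
    return y, {"hidden_features": cache["H"], "h": cache["h"]}


def predict_scores(features: Sequence[np.ndarray], params: NetworkParams) -> np.ndarray:
    return _forward_cache(features, params)[0]


def predict(features: Sequence[np.ndarray], params: NetworkParams,
            threshold: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Binary calls (positive iff y > threshold) plus the raw scores.

    The default threshold 0 is the midpoint of the tanh output range;
    sweeping it traces out the model's ROC curve.
    """
    y = predict_scores(features, params)
    return y > threshold, y


def _zero_like(params: NetworkParams) -> NetworkParams:
    return NetworkParams(
        encoders=[DenseLayerParams(np.zeros_like(e.W), np.zeros_like(e.b))
                  for e in params.encoders],
        hidden1=DenseLayerParams(np.zeros_like(params.hidden1.W),
                                 np.zeros_like(params.hidden1.b)),
        hidden2=DenseLayerParams(np.zeros_like(params.hidden2.W),
                                 np.zeros_like(params.hidden2.b)),
    )


def loss_and_gradients(
    features: Sequence[np.ndarray],
    labels: Sequence[float],
    params: NetworkParams,
    loss: str = "mse",
) -> tuple[float, NetworkParams]:
    """Batch loss and the gradient of every parameter (reverse mode).

    Labels are +-1 (malignant/benign).  ``mse`` is mean squared error
    between the tanh output and the label; ``bce`` is binary cross-entropy
    with a sigmoid head against labels mapped to {0, 1}.
    """
    t = np.asarray(labels, dtype=float)
    if t.size == 0:
        raise ValueError("empty batch")
    y, cache = _forward_cache(features, params, loss=loss)
    B = t.size
    if y.shape[0] != B:
        raise ValueError("labels do not match batch size")
    n_feat = len(params.encoders)

    if loss == "mse":
        value = float(np.mean((y - t) ** 2))
        dy = 2.0 * (y - t) / B                 # dL/dy
        dA2 = (dy * (1.0 - y**2))[:, None]     # tanh head
    else:
        t01 = (t + 1.0) / 2.0
        eps = 1e-12
        value = float(-np.mean(t01 * np.log(y + eps)
                               + (1 - t01) * np.log(1 - y + eps)))
        dA2 = ((y - t01) / B)[:, None]         # sigmoid + BCE shortcut

    grads = _zero_like(params)
    H1, h, H, X = cache["H1"], cache["h"], cache["H"], cache["X"]
    grads.hidden2.W[:] = H1.T @ dA2
    grads.hidden2.b[:] = dA2.sum(axis=0)
    dH1 = dA2 @ params.hidden2.W.T
    dA1 = dH1 * (1.0 - H1**2)
    grads.hidden1.W[:] = h.T @ dA1
    grads.hidden1.b[:] = dA1.sum(axis=0)
    dh = dA1 @ params.hidden1.W.T
    dHi = dh / n_feat                          # mean pooling spreads evenly
    for i, enc in enumerate(params.encoders):
        dAi = dHi * (1.0 - H[i] ** 2)
        grads.encoders[i].W[:] = X[i].T @ dAi
        grads.encoders[i].b[:] = dAi.sum(axis=0)
    return value, grads


def _sgd_step(params: NetworkParams, grads: NetworkParams, lr: float) -> None:
    for p, g in zip(params.encoders, grads.encoders):
        p.W -= lr * g.W
        p.b -= lr * g.b
    for name in ("hidden1", "hidden2"):
        getattr(params, name).W -= lr * getattr(grads, name).W
        getattr(params, name).b -= lr * getattr(grads, name).b


def stratified_split(labels: Sequence, fractions: Sequence[float], seed: int
                     ) -> list[np.ndarray]:
    """Disjoint index sets with the class ratio preserved in each part.

    ``fractions`` must sum to 1; remainders go to the first part.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[] for _ in fractions]
    for value in np.unique(y):
        idx = np.flatnonzero(y == value)
        rng.shuffle(idx)
        bounds = np.floor(np.cumsum(fractions) * len(idx)).astype(int)
        start = 0
        for k, stop in enumerate(bounds):
            parts[k].extend(idx[start:stop])
            start = stop
        parts[0].extend(idx[start:])
    return [np.sort(np.asarray(p, dtype=int)) for p in parts]


def _take(features: Sequence[np.ndarray], idx: np.ndarray) -> list[np.ndarray]:
    return [f[idx] for f in features]


def train(
    features: Sequence[np.ndarray],
    labels: Sequence[float],
    config: TrainConfig,
    val_features: Sequence[np.ndarray] | None = None,
    val_labels: Sequence[float] | None = None,
) -> tuple[NetworkParams, list[dict]]:
    """Mini-batch gradient descent; returns the parameters at the best
    validation loss and a per-epoch training log.

    If no validation set is passed, a seeded stratified ``val_fraction``
    split is carved out of the data.  Everything (init, shuffling, split) is
    driven by ``config.seed``, so identical configs give bit-identical runs.
    """
    t = np.asarray(labels, dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("training data must contain both classes")
    feats = [np.atleast_2d(np.asarray(f, dtype=float)) for f in features]
    if val_features is None:
        tr_idx, va_idx = stratified_split(
            t, [1.0 - config.val_fraction, config.val_fraction], config.seed)
        Xtr, ttr = _take(feats, tr_idx), t[tr_idx]
        Xva, tva = _take(feats, va_idx), t[va_idx]
    else:
        Xtr, ttr = feats, t
        Xva = [np.atleast_2d(np.asarray(f, dtype=float)) for f in val_features]
        tva = np.asarray(val_labels, dtype=float)

    params = init_params([f.shape[1] for f in feats], config.hidden_dim,
                         seed=config.seed, init_scale=config.init_scale)
    rng = np.random.default_rng(config.seed + 1)
    n = ttr.size
    best_val = math.inf
    best_params = params.copy()
    log: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            value, grads = loss_and_gradients(
                _take(Xtr, batch), ttr[batch], params, loss=config.loss)
            if not math.isfinite(value):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}")
            _sgd_step(params, grads, config.learning_rate)
            epoch_loss += value
            n_batches += 1
        val_loss, _ = loss_and_gradients(Xva, tva, params, loss=config.loss)
        if not math.isfinite(val_loss):
            raise TrainingDivergedError(f"non-finite validation loss at epoch {epoch}")
        if val_loss < best_val:
            best_val = val_loss
            best_params = params.copy()
        log.append({"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1),
                    "val_loss": val_loss})
    return best_params, log


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_MODEL_FORMAT_VERSION = 1


def params_to_dict(params: NetworkParams) -> dict:
    return {
        "encoders": [{"W": e.W.tolist(), "b": e.b.tolist()} for e in params.encoders],
        "hidden1": {"W": params.hidden1.W.tolist(), "b": params.hidden1.b.tolist()},
        "hidden2": {"W": params.hidden2.W.tolist(), "b": params.hidden2.b.tolist()},
    }


def params_from_dict(d: dict) -> NetworkParams:
    return NetworkParams(
        encoders=[DenseLayerParams(np.asarray(e["W"]), np.asarray(e["b"]))
                  for e in d["encoders"]],
        hidden1=DenseLayerParams(np.asarray(d["hidden1"]["W"]),
                                 np.asarray(d["hidden1"]["b"])),
        hidden2=DenseLayerParams(np.asarray(d["hidden2"]["W"]),
                                 np.asarray(d["hidden2"]["b"])),
    )


def save_model(path, params: NetworkParams, specs, stats, extra: dict | None = None
               ) -> None:
    """Versioned JSON bundle: parameters + feature specs + normalization."""
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "params": params_to_dict(params),
        "feature_specs": [s.to_dict() for s in specs],
        "normalization": stats.to_dict(),
        "extra": extra or {},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path):
    """Inverse of :func:`save_model`; returns (params, specs, stats, extra)."""
    from nodulediag.preprocess import FeatureSpec, NormalizationStats

    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format {payload.get('format_version')}")
    return (
        params_from_dict(payload["params"]),
        [FeatureSpec.from_dict(d) for d in payload["feature_specs"]],
        NormalizationStats.from_dict(payload["normalization"]),
        payload.get("extra", {}),
    )
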