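"""Stacked autoencoder classifier, implemented directly in NumPy.

The network is a stack of sigmoid affine layers followed by a two-class
softmax head.  Training has two phases:

1. **Greedy layer-wise pretraining.**  Each hidden layer is trained as a
   plain autoencoder on the activations of the layer below: the encoder
   ``h = f(W_enc x + b_enc)`` and a throwaway decoder
   ``x_hat = f(W_dec h + b_dec)`` are fitted by momentum gradient descent
   on mean squared reconstruction error.  Decoder weights are untied from
   the encoder and play no role after pretraining.

2. **Supervised fine-tuning.**  The full encoder stack plus the softmax
   head is trained end-to-end by momentum gradient descent on the
   cross-entropy of the class probabilities.

All randomness (weight init, mini-batch shuffling) flows from explicit
integer seeds, so a fixed seed gives a bitwise-reproducible model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


def sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically stable two-branch form
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class LayerParams:
    """Encoder and (pretraining-only) decoder parameters of one layer."""

    W_enc: np.ndarray  # (out, in)
    b_enc: np.ndarray  # (out,)
    W_dec: np.ndarray  # (in, out)
    b_dec: np.ndarray  # (in,)


@dataclass
class TrainConfig:
    """Gradient-descent settings shared by pretraining and fine-tuning.

    The defaults are conventional for sigmoid autoencoder stacks at this
    input scale: a larger rate for the layer-wise reconstruction phase, a
    smaller one for the supervised phase, and a moderate momentum.
    """

    learning_rate: float = 0.5
    finetune_learning_rate: float = 0.1
    momentum: float = 0.5
    pretrain_epochs: int = 20
    finetune_epochs: int = 50
    batch_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 and self.learning_rate != 0:
            raise ValueError("learning_rate must be >= 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        for name in ("pretrain_epochs", "finetune_epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


class SAEModel:
    """A stack of sigmoid layers with a two-class softmax output head."""

    def __init__(self, layer_sizes: list[int], activation: str = "sigmoid", seed: int = 0):
        if len(layer_sizes) < 2:
            raise ValueError("need at least input and output sizes")
        if any(s <= 0 for s in layer_sizes):
            raise ValueError(f"layer sizes must be positive, got {layer_sizes}")
        if layer_sizes[-1] != 2:
            raise ValueError("output layer must have 2 units (interaction / non-interaction)")
        if activation != "sigmoid":
            raise ValueError(f"unsupported activation {activation!r}")
        self.layer_sizes = list(layer_sizes)
        self.activation = activation
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.layers: list[LayerParams] = []
        for fan_in, fan_out in zip(layer_sizes[:-2], layer_sizes[1:-1]):
            limit = 4.0 * np.sqrt(6.0 / (fan_in + fan_out))
            self.layers.append(
                LayerParams(
                    W_enc=rng.uniform(-limit, limit, size=(fan_out, fan_in)),
                    b_enc=np.zeros(fan_out),
                    W_dec=rng.uniform(-limit, limit, size=(fan_in, fan_out)),
                    b_dec=np.zeros(fan_in),
                )
            )
        # softmax head starts at zero: initial prediction is (0.5, 0.5)
        self.W_head = np.zeros((2, layer_sizes[-2]))
        self.b_head = np.zeros(2)

    # ------------------------------------------------------------------ forward

    def forward(self, X: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        """All layer activations (input first) and softmax class probabilities."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.layer_sizes[0]:
            raise ValueError(
                f"input dimension {X.shape[1]} != model input size {self.layer_sizes[0]}"
            )
        activations = [X]
        a = X
        for layer in self.layers:
            a = sigmoid(a @ layer.W_enc.T + layer.b_enc)
            activations.append(a)
        probs = softmax(a @ self.W_head.T + self.b_head)
        return activations, probs

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class labels; an exact probability tie goes to the negative class."""
        probs = self.predict_proba(X)
        return (probs[:, 1] > probs[:, 0]).astype(int)

    # ------------------------------------------------------------- pretraining

    def pretrain_layer(self, layer_index: int, X: np.ndarray, cfg: TrainConfig) -> list[float]:
        """Train one layer as an autoencoder on ``X``; returns per-epoch MSE."""
        layer = self.layers[layer_index]
        X = np.asarray(X, dtype=float)
        if X.shape[1] != layer.W_enc.shape[1]:
            raise ValueError(
                f"layer {layer_index}: input dimension {X.shape[1]} != {layer.W_enc.shape[1]}"
            )
        rng = np.random.default_rng((cfg.seed, layer_index))
        vel = {k: np.zeros_like(getattr(layer, k)) for k in ("W_enc", "b_enc", "W_dec", "b_dec")}
        trace: list[float] = []
        n = X.shape[0]
        for epoch in range(cfg.pretrain_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                xb = X[order[start : start + cfg.batch_size]]
                m, d = xb.shape
                h = sigmoid(xb @ layer.W_enc.T + layer.b_enc)
                xhat = sigmoid(h @ layer.W_dec.T + layer.b_dec)
                diff = xhat - xb
                loss = float((diff**2).mean())
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite reconstruction loss at epoch {epoch}"
                    )
                losses.append((loss, m))
                dz2 = (2.0 / (m * d)) * diff * xhat * (1 - xhat)
                g = {
                    "W_dec": dz2.T @ h,
                    "b_dec": dz2.sum(axis=0),
                }
                dh = dz2 @ layer.W_dec
                dz1 = dh * h * (1 - h)
                g["W_enc"] = dz1.T @ xb
                g["b_enc"] = dz1.sum(axis=0)
                for k, grad in g.items():
                    vel[k] = cfg.momentum * vel[k] - cfg.learning_rate * grad
                    getattr(layer, k)[...] += vel[k]
            trace.append(sum(l * m for l, m in losses) / n)
        return trace

    def pretrain(self, X: np.ndarray, cfg: TrainConfig) -> list[list[float]]:
        """Greedy layer-wise pretraining of every hidden layer in turn."""
        traces = []
        a = np.asarray(X, dtype=float)
        for i, layer in enumerate(self.layers):
            traces.append(self.pretrain_layer(i, a, cfg))
            a = sigmoid(a @ layer.W_enc.T + layer.b_enc)
        return traces

    # ------------------------------------------------------------- fine-tuning

    def _finetune_grads(
        self, X: np.ndarray, y: np.ndarray
    ) -> tuple[float, list[dict[str, np.ndarray]], np.ndarray, np.ndarray]:
        """Cross-entropy loss and gradients for all encoder + head parameters."""
        m = X.shape[0]
        activations, probs = self.forward(X)
        onehot = np.zeros((m, 2))
        onehot[np.arange(m), y] = 1.0
        eps = 1e-12
        loss = float(-(onehot * np.log(probs + eps)).sum() / m)
        dlogits = (probs - onehot) / m
        g_head_W = dlogits.T @ activations[-1]
        g_head_b = dlogits.sum(axis=0)
        delta = dlogits @ self.W_head
        layer_grads: list[dict[str, np.ndarray]] = [None] * len(self.layers)  # type: ignore
        for i in range(len(self.layers) - 1, -1, -1):
            a_out = activations[i + 1]
            dz = delta * a_out * (1 - a_out)
            layer_grads[i] = {"W_enc": dz.T @ activations[i], "b_enc": dz.sum(axis=0)}
            if i > 0:
                delta = dz @ self.layers[i].W_enc
        return loss, layer_grads, g_head_W, g_head_b

    def fine_tune(self, X: np.ndarray, y: np.ndarray, cfg: TrainConfig) -> list[float]:
        """End-to-end supervised training; returns per-epoch mean cross-entropy."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have different numbers of samples")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")
        y = y.astype(int)
        rng = np.random.default_rng((cfg.seed, len(self.layers)))
        vel_layers = [
            {k: np.zeros_like(getattr(l, k)) for k in ("W_enc", "b_enc")} for l in self.layers
        ]
        vel_head_W = np.zeros_like(self.W_head)
        vel_head_b = np.zeros_like(self.b_head)
        lr = cfg.finetune_learning_rate
        trace: list[float] = []
        n = X.shape[0]
        for epoch in range(cfg.finetune_epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                loss, layer_grads, gW, gb = self._finetune_grads(X[idx], y[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(f"non-finite loss at epoch {epoch}")
                total += loss * idx.size
                for layer, g, vel in zip(self.layers, layer_grads, vel_layers):
                    for k in ("W_enc", "b_enc"):
                        vel[k] = cfg.momentum * vel[k] - lr * g[k]
                        getattr(layer, k)[...] += vel[k]
                vel_head_W = cfg.momentum * vel_head_W - lr * gW
                vel_head_b = cfg.momentum * vel_head_b - lr * gb
                self.W_head += vel_head_W
                self.b_head += vel_head_b
            trace.append(total / n)
        return trace

    def fit(self, X: np.ndarray, y: np.ndarray, cfg: TrainConfig) -> dict:
        """Pretrain every layer, then fine-tune; returns both loss traces."""
        pre = self.pretrain(X, cfg)
        fine = self.fine_tune(X, y, cfg)
        return {"pretrain": pre, "finetune": fine}

    # ---------------------------------------------------------- serialization

    def to_dict(self) -> dict:
        return {
            "layer_sizes": self.layer_sizes,
            "activation": self.activation,
            "seed": self.seed,
            "layers": [
                {
                    "W_enc": l.W_enc.tolist(),
                    "b_enc": l.b_enc.tolist(),
                    "W_dec": l.W_dec.tolist(),
                    "b_dec": l.b_dec.tolist(),
                }
                for l in self.layers
            ],
            "W_head": self.W_head.tolist(),
            "b_head": self.b_head.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SAEModel":
        model = cls(d["layer_sizes"], d["activation"], d.get("seed", 0))
        for layer, ld in zip(model.layers, d["layers"]):
            layer.W_enc = np.asarray(ld["W_enc"], dtype=float)
            layer.b_enc = np.asarray(ld["b_enc"], dtype=float)
            layer.W_dec = np.asarray(ld["W_dec"], dtype=float)
            layer.b_dec = np.asarray(ld["b_dec"], dtype=float)
        model.W_head = np.asarray(d["W_head"], dtype=float)
        model.b_head = np.asarray(d["b_head"], dtype=float)
        return model

    def save(self, path, extra: dict | None = None) -> None:
        payload = {"model": self.to_dict()}
        if extra:
            payload.update(extra)
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> tuple["SAEModel", dict]:
        with open(path) as fh:
            payload = json.load(fh)
        model = cls.from_dict(payload["model"])
        meta = {k: v for k, v in payload.items() if k != "model"}
        return model, meta


def init_model(layer_sizes: list[int], activation: str = "sigmoid", seed: int = 0) -> SAEModel:
    """Construct a model with seeded symmetric-uniform weights, zero biases."""
    return SAEModel(layer_sizes, activation, seed)


# --------------------------------------------------------------- verification


def _param_refs(model: SAEModel, objective: str, layer_index: int):
    if objective == "finetune":
        refs = []
        for l in model.layers:
            refs += [l.W_enc, l.b_enc]
        refs += [model.W_head, model.b_head]
        return refs
    layer = model.layers[layer_index]
    return [layer.W_enc, layer.b_enc, layer.W_dec, layer.b_dec]


def _pretrain_loss(model: SAEModel, layer_index: int, X: np.ndarray) -> float:
    layer = model.layers[layer_index]
    h = sigmoid(X @ layer.W_enc.T + layer.b_enc)
    xhat = sigmoid(h @ layer.W_dec.T + layer.b_dec)
    return float(((xhat - X) ** 2).mean())


def _pretrain_grads(model: SAEModel, layer_index: int, X: np.ndarray):
    layer = model.layers[layer_index]
    m, d = X.shape
    h = sigmoid(X @ layer.W_enc.T + layer.b_enc)
    xhat = sigmoid(h @ layer.W_dec.T + layer.b_dec)
    dz2 = (2.0 / (m * d)) * (xhat - X) * xhat * (1 - xhat)
    dh = dz2 @ layer.W_dec
    dz1 = dh * h * (1 - h)
    return [dz1.T @ X, dz1.sum(axis=0), dz2.T @ h, dz2.sum(axis=0)]


def gradient_check(
    model: SAEModel,
    X: np.ndarray,
    y: np.ndarray | None = None,
    epsilon: float = 1e-5,
    objective: str = "finetune",
    layer_index: int = 0,
) -> float:
    """Max relative discrepancy between analytic and central-difference gradients.

    ``objective`` selects the fine-tuning cross-entropy (requires ``y``) or
    one layer's pretraining reconstruction loss.  Intended for small models;
    the cost is two loss evaluations per parameter.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if objective == "finetune":
        if y is None:
            raise ValueError("finetune gradient check requires labels")
        y = np.asarray(y, dtype=int)
        _, layer_grads, gW, gb = model._finetune_grads(X, y)
        analytic = []
        for g in layer_grads:
            analytic += [g["W_enc"], g["b_enc"]]
        analytic += [gW, gb]
        loss_fn = lambda: model._finetune_grads(X, y)[0]
    elif objective == "pretrain":
        for layer in model.layers[:layer_index]:
            X = sigmoid(X @ layer.W_enc.T + layer.b_enc)
        analytic = _pretrain_grads(model, layer_index, X)
        loss_fn = lambda: _pretrain_loss(model, layer_index, X)
    else:
        raise ValueError(f"unknown objective {objective!r}")

    worst = 0.0
    for param, grad in zip(_param_refs(model, objective, layer_index), analytic):
        flat = param.ravel()
        gflat = grad.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + epsilon
            hi = loss_fn()
            flat[i] = orig - epsilon
            lo = loss_fn()
            flat[i] = orig
            numeric = (hi - lo) / (2 * epsilon)
            denom = max(abs(numeric) + abs(gflat[i]), 1e-8)
            worst = max(worst, abs(numeric - gflat[i]) / denom)
    return worst
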