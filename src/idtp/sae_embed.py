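"""Stacked auto-encoder embedding of the protein feature matrix.

An auto-encoder (AE) maps an input x to a hidden code y = f(Wx + b) and
reconstructs it as z = g(W~y + b~).  Stacking AEs greedily — each one
trained to reconstruct the hidden code of the previous — yields a deep
encoder whose narrowest (bottleneck) layer provides a low-dimensional
embedding of the data.  The default architecture mirrors the framework's
reference setup: layer widths 283-140-10-140-283, i.e. two stacked AEs
with a 10-dimensional bottleneck, trained with minibatch Adadelta on the
mean squared reconstruction error and stopped early when the validation
reconstruction error stops improving.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .feature_table import FeatureMatrix


class SAEError(ValueError):
    pass


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def _sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


# name -> (forward, derivative as a function of (preactivation, output))
ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "sigmoid": (_sigmoid, lambda a, out: out * (1.0 - out)),
    "linear": (lambda a: a, lambda a, out: np.ones_like(a)),
    "relu": (lambda a: np.maximum(a, 0.0), lambda a, out: (a > 0).astype(a.dtype)),
}


def _activation(name: str) -> tuple[Callable, Callable]:
    try:
        return ACTIVATIONS[name]
    except KeyError:
        raise SAEError(
            f"unknown activation {name!r}; known: {sorted(ACTIVATIONS)}"
        )


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def mse_loss(x: np.ndarray, z: np.ndarray) -> float:
    """Squared reconstruction error ||x - z||^2 (summed over components)."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    return float(np.sum((x - z) ** 2))


def xent_loss(x: np.ndarray, z: np.ndarray, eps: float = 1e-7) -> float:
    """Summed binary cross-entropy -sum(x ln z + (1-x) ln(1-z)).

    ``x`` must be 0/1; ``z`` is clipped into (eps, 1-eps).
    """
    x = np.asarray(x, dtype=float)
    if not np.all((x == 0.0) | (x == 1.0)):
        raise SAEError("cross-entropy target must be binary (0/1)")
    z = np.clip(np.asarray(z, dtype=float), eps, 1.0 - eps)
    return float(-np.sum(x * np.log(z) + (1.0 - x) * np.log1p(-z)))


def _loss_and_grad(name: str, x: np.ndarray, z: np.ndarray, eps: float = 1e-7):
    """Batch-mean loss and its gradient w.r.t. z for a (n, d) batch."""
    n = x.shape[0]
    if name == "mean_square":
        diff = z - x
        return float(np.sum(diff * diff) / n), 2.0 * diff / n
    if name == "cross_entropy":
        zc = np.clip(z, eps, 1.0 - eps)
        loss = float(-np.sum(x * np.log(zc) + (1.0 - x) * np.log1p(-zc)) / n)
        grad = (zc - x) / (zc * (1.0 - zc)) / n
        return loss, grad
    raise SAEError(f"unknown loss {name!r}")


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class Optimizer:
    """Per-parameter first-order update rule applied to a list of arrays."""

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, lr: float = 0.1):
        self.lr = lr

    def step(self, params, grads):
        for p, g in zip(params, grads):
            p -= self.lr * g


class Adadelta(Optimizer):
    """Adadelta with its canonical defaults (decay 0.95, epsilon 1e-6)."""

    def __init__(self, rho: float = 0.95, eps: float = 1e-6):
        self.rho = rho
        self.eps = eps
        self._acc_g: list[np.ndarray] | None = None
        self._acc_dx: list[np.ndarray] | None = None

    def step(self, params, grads):
        if self._acc_g is None:
            self._acc_g = [np.zeros_like(p) for p in params]
            self._acc_dx = [np.zeros_like(p) for p in params]
        for p, g, ag, adx in zip(params, grads, self._acc_g, self._acc_dx):
            ag *= self.rho
            ag += (1.0 - self.rho) * g * g
            dx = -np.sqrt(adx + self.eps) / np.sqrt(ag + self.eps) * g
            adx *= self.rho
            adx += (1.0 - self.rho) * dx * dx
            p += dx


class Adam(Optimizer):
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None
        self._t = 0

    def step(self, params, grads):
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self._t += 1
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            mhat = m / (1.0 - self.beta1**self._t)
            vhat = v / (1.0 - self.beta2**self._t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def make_optimizer(name: str, **kwargs) -> Optimizer:
    registry = {"sgd": SGD, "adadelta": Adadelta, "adam": Adam}
    try:
        return registry[name](**kwargs)
    except KeyError:
        raise SAEError(f"unknown optimizer {name!r}; known: {sorted(registry)}")


# ---------------------------------------------------------------------------
# layers and model
# ---------------------------------------------------------------------------

@dataclass
class AELayer:
    """One auto-encoder: encoder y = f(Wx+b), decoder z = g(W~y+b~)."""

    W: np.ndarray        # (hidden, in)
    b: np.ndarray        # (hidden,)
    W_tilde: np.ndarray  # (in, hidden)
    b_tilde: np.ndarray  # (in,)
    f: str = "sigmoid"
    g: str = "linear"

    def __post_init__(self) -> None:
        h, d = self.W.shape
        if self.b.shape != (h,) or self.W_tilde.shape != (d, h) or self.b_tilde.shape != (d,):
            raise SAEError(
                f"inconsistent AE layer shapes: W {self.W.shape}, b {self.b.shape}, "
                f"W~ {self.W_tilde.shape}, b~ {self.b_tilde.shape}"
            )
        _activation(self.f)
        _activation(self.g)


def encode(x: np.ndarray, layer: AELayer) -> np.ndarray:
    """Hidden code f(Wx + b); accepts a vector or an (n, d) batch."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != layer.W.shape[1]:
        raise SAEError(
            f"input width {x.shape[-1]} does not match encoder input {layer.W.shape[1]}"
        )
    fwd, _ = _activation(layer.f)
    return fwd(x @ layer.W.T + layer.b)


def decode(y: np.ndarray, layer: AELayer) -> np.ndarray:
    """Reconstruction g(W~y + b~); accepts a vector or an (n, h) batch."""
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != layer.W_tilde.shape[1]:
        raise SAEError(
            f"code width {y.shape[-1]} does not match decoder input {layer.W_tilde.shape[1]}"
        )
    fwd, _ = _activation(layer.g)
    return fwd(y @ layer.W_tilde.T + layer.b_tilde)


@dataclass
class SAEModel:
    layers: list[AELayer]
    layer_sizes: list[int]
    bottleneck_index: int
    training_log: list[list[tuple[int, float, float]]] = field(default_factory=list)
    # training_log[k] = per-epoch (epoch, train error, validation error) of AE k

    @property
    def bottleneck_dim(self) -> int:
        return self.layer_sizes[self.bottleneck_index]

    def encode_to_bottleneck(self, X: np.ndarray) -> np.ndarray:
        out = np.asarray(X, dtype=float)
        for layer in self.layers:
            out = encode(out, layer)
        return out


@dataclass
class SAETrainConfig:
    """Training settings for each stacked auto-encoder."""

    nb_epoch: int = 100
    batch_size: int = 100
    optimizer: str = "adadelta"
    optimizer_kwargs: dict = field(default_factory=dict)
    loss: str = "mean_square"
    training_ratio: float = 0.7
    validation_ratio: float = 0.3
    patience: int = 5
    min_delta: float = 1e-4
    hidden_activation: str = "sigmoid"
    output_activation: str = "linear"
    fine_tune: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.training_ratio + self.validation_ratio - 1.0) > 1e-9:
            raise SAEError("training_ratio + validation_ratio must equal 1")
        if self.nb_epoch < 1 or self.batch_size < 1:
            raise SAEError("nb_epoch and batch_size must be >= 1")


def _glorot_uniform(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_out, fan_in))


def _forward(X, weights, biases, acts):
    """Forward pass through a plain dense stack, caching layer outputs."""
    outs = [X]
    pres = []
    for W, b, act in zip(weights, biases, acts):
        a = outs[-1] @ W.T + b
        fwd, _ = _activation(act)
        pres.append(a)
        outs.append(fwd(a))
    return pres, outs


def _backward(grad_out, pres, outs, weights, acts):
    """Gradients of a batch loss w.r.t. every weight and bias."""
    gW, gb = [], []
    delta = grad_out
    for k in range(len(weights) - 1, -1, -1):
        _, dact = _activation(acts[k])
        delta = delta * dact(pres[k], outs[k + 1])
        gW.append(delta.T @ outs[k])
        gb.append(delta.sum(axis=0))
        if k > 0:
            delta = delta @ weights[k]
    gW.reverse()
    gb.reverse()
    return gW, gb


def _train_network(
    X: np.ndarray,
    weights: list[np.ndarray],
    biases: list[np.ndarray],
    acts: list[str],
    config: SAETrainConfig,
    rng: np.random.Generator,
) -> list[tuple[int, float, float]]:
    """Minibatch-train a dense reconstruction network in place.

    The network maps X back onto itself (targets = inputs).  Rows are
    split once into training/validation per the configured ratio; after
    each epoch the validation reconstruction error is evaluated and
    training stops early once it has failed to improve on its running
    minimum by ``min_delta`` for ``patience`` consecutive epochs.  The
    best-validation weights are restored on exit.
    """
    n = X.shape[0]
    perm = rng.permutation(n)
    n_train = max(1, int(np.floor(config.training_ratio * n + 0.5)))
    n_train = min(n_train, n - 1) if n > 1 else 1
    train_idx, val_idx = perm[:n_train], perm[n_train:]
    X_train = X[train_idx]
    X_val = X[val_idx] if len(val_idx) else X_train

    params = [*weights, *biases]
    optimizer = make_optimizer(config.optimizer, **config.optimizer_kwargs)

    def eval_error(data: np.ndarray) -> float:
        _, outs = _forward(data, weights, biases, acts)
        loss, _ = _loss_and_grad(config.loss, data, outs[-1])
        return loss

    log: list[tuple[int, float, float]] = []
    best_val = np.inf
    best_params = [p.copy() for p in params]
    stale = 0
    for epoch in range(config.nb_epoch):
        order = rng.permutation(len(X_train))
        for start in range(0, len(X_train), config.batch_size):
            batch = X_train[order[start : start + config.batch_size]]
            pres, outs = _forward(batch, weights, biases, acts)
            _, grad_out = _loss_and_grad(config.loss, batch, outs[-1])
            gW, gb = _backward(grad_out, pres, outs, weights, acts)
            optimizer.step(params, [*gW, *gb])
        train_err = eval_error(X_train)
        val_err = eval_error(X_val)
        log.append((epoch, train_err, val_err))
        if val_err < best_val - config.min_delta:
            best_val = val_err
            best_params = [p.copy() for p in params]
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    for p, best in zip(params, best_params):
        p[...] = best
    return log


def train_sae(
    features: FeatureMatrix | np.ndarray,
    config: SAETrainConfig | None = None,
    sizes: Sequence[int] = (283, 140, 10, 140, 283),
) -> SAEModel:
    """Greedily train a stack of auto-encoders on the feature matrix.

    ``sizes`` lists the unit counts of the full (palindromic) network;
    the middle entry is the bottleneck.  Each AE is trained to
    reconstruct the previous AE's hidden code; with ``fine_tune`` set in
    the config, the unrolled encoder-decoder stack is afterwards trained
    end to end.  Deterministic given ``config.seed``.
    """
    config = config or SAETrainConfig()
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    if X.size == 0:
        raise SAEError("empty feature matrix")
    sizes = list(sizes)
    if len(sizes) < 3 or len(sizes) % 2 == 0:
        raise SAEError("layer sizes must have odd length >= 3 (encoder/bottleneck/decoder)")
    if sizes != sizes[::-1]:
        raise SAEError(f"layer sizes must be palindromic, got {sizes}")
    if sizes[0] != X.shape[1]:
        raise SAEError(
            f"first layer size {sizes[0]} must equal the feature dimension {X.shape[1]}"
        )
    bottleneck_index = len(sizes) // 2
    rng = np.random.default_rng(config.seed)

    layers: list[AELayer] = []
    logs: list[list[tuple[int, float, float]]] = []
    current = X
    for k in range(bottleneck_index):
        d_in, d_hidden = sizes[k], sizes[k + 1]
        W = _glorot_uniform(rng, d_hidden, d_in)
        b = np.zeros(d_hidden)
        W_tilde = _glorot_uniform(rng, d_in, d_hidden)
        b_tilde = np.zeros(d_in)
        log = _train_network(
            current,
            [W, W_tilde],
            [b, b_tilde],
            [config.hidden_activation, config.output_activation],
            config,
            rng,
        )
        layer = AELayer(W=W, b=b, W_tilde=W_tilde, b_tilde=b_tilde,
                        f=config.hidden_activation, g=config.output_activation)
        layers.append(layer)
        logs.append(log)
        current = encode(current, layer)

    if config.fine_tune:
        # unroll encoders then decoders and train the whole stack end to end
        weights = [l.W for l in layers] + [l.W_tilde for l in reversed(layers)]
        biases = [l.b for l in layers] + [l.b_tilde for l in reversed(layers)]
        acts = [l.f for l in layers] + [l.g for l in reversed(layers)]
        logs.append(_train_network(X, weights, biases, acts, config, rng))

    return SAEModel(layers=layers, layer_sizes=sizes,
                    bottleneck_index=bottleneck_index, training_log=logs)


def embed(features: FeatureMatrix, model: SAEModel) -> FeatureMatrix:
    """Map rows through the encoder stack to the bottleneck representation."""
    if features.d != model.layer_sizes[0]:
        raise SAEError(
            f"feature dimension {features.d} does not match model input "
            f"{model.layer_sizes[0]}"
        )
    Z = model.encode_to_bottleneck(features.values)
    return FeatureMatrix(
        values=Z,
        column_provenance=[("embedding", f"dim{j}") for j in range(Z.shape[1])],
        row_ids=list(features.row_ids),
        row_labels=list(features.row_labels),
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_sae(model: SAEModel, path: str | Path) -> None:
    doc = {
        "layer_sizes": model.layer_sizes,
        "bottleneck_index": model.bottleneck_index,
        "layers": [
            {
                "W": l.W.tolist(), "b": l.b.tolist(),
                "W_tilde": l.W_tilde.tolist(), "b_tilde": l.b_tilde.tolist(),
                "f": l.f, "g": l.g,
            }
            for l in model.layers
        ],
        "training_log": [[list(rec) for rec in log] for log in model.training_log],
    }
    Path(path).write_text(json.dumps(doc))


def load_sae(path: str | Path) -> SAEModel:
    doc = json.loads(Path(path).read_text())
    layers = [
        AELayer(
            W=np.asarray(l["W"], dtype=float),
            b=np.asarray(l["b"], dtype=float),
            W_tilde=np.asarray(l["W_tilde"], dtype=float),
            b_tilde=np.asarray(l["b_tilde"], dtype=float),
            f=l["f"], g=l["g"],
        )
        for l in doc["layers"]
    ]
    return SAEModel(
        layers=layers,
        layer_sizes=list(doc["layer_sizes"]),
        bottleneck_index=int(doc["bottleneck_index"]),
        training_log=[[tuple(rec) for rec in log] for log in doc["training_log"]],
    )


def write_training_log(model: SAEModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ae\tepoch\ttrain_error\tvalidation_error\n")
        for k, log in enumerate(model.training_log):
            for epoch, tr, va in log:
                fh.write(f"{k}\t{epoch}\t{tr:.10g}\t{va:.10g}\n")
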