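"""A small convolutional network implemented from its forward/backward algebra.

The network maps a 6x6x1 feature grid through two same-padded 3x3
convolutions (32 and 64 channels, ReLU), two overlapping 2x2 stride-1 max
pools, two 128-unit ReLU dense layers, and a 2-way softmax output:

    6x6x1 -> 6x6x32 -> 5x5x32 -> 5x5x64 -> 4x4x64 -> 1024 -> 128 -> 128 -> 2

Training is plain batch gradient descent on softmax cross-entropy.  The
output-layer error is ``delta_L = a_L - y``; dense layers back-propagate
``delta = W^T delta_next (.) relu'(z)``; convolution layers propagate the
error by full correlation with the 180-degree-rotated kernels (realised here
through the im2col transpose); max-pool layers route each error only to its
recorded argmax position, accumulating additively where stride-1 windows
overlap.  Parameter updates subtract ``lr`` times the *batch-summed*
per-sample gradients — no momentum, no weight decay.

Forward convolutions use the cross-correlation convention with one bias per
output channel.  All arithmetic is float64 so the analytic gradients can be
checked against central finite differences to tight tolerance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

from .errors import (ArchitectureError, ConfigurationError, DivergenceError,
                     UsageError)

__all__ = [
    "LayerSpec", "NetworkSpec", "TrainConfig", "TrainingHistory", "Network",
    "default_network_spec", "mini_network_spec",
    "conv_forward", "conv_backward", "max_pool_forward", "pool_backward",
    "dense_forward", "dense_backward", "softmax", "relu",
    "update_params", "train_network", "extract_features", "predict_softmax",
    "cross_entropy", "gradient_check",
]


# ---------------------------------------------------------------------------
# elementwise pieces
# ---------------------------------------------------------------------------

def relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max subtraction for numerical stability."""
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, y_onehot: np.ndarray) -> float:
    """Mean cross-entropy of predicted class probabilities."""
    eps = 1e-300
    return float(-np.mean(np.sum(y_onehot * np.log(probs + eps), axis=1)))


# ---------------------------------------------------------------------------
# im2col helpers
# ---------------------------------------------------------------------------

def _pad_same(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    pt, pl = (kh - 1) // 2, (kw - 1) // 2
    pb, pr = kh - 1 - pt, kw - 1 - pl
    return np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    n, H, W, C = xp.shape
    oh = (H - kh) // stride + 1
    ow = (W - kw) // stride + 1
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, oh, ow, kh, kw, C),
        strides=(s[0], s[1] * stride, s[2] * stride, s[1], s[2], s[3]),
        writeable=False,
    )
    return view.reshape(n * oh * ow, kh * kw * C), oh, ow


def _col2im(dcols: np.ndarray, xp_shape, kh: int, kw: int, stride: int,
            oh: int, ow: int) -> np.ndarray:
    n, H, W, C = xp_shape
    dxp = np.zeros(xp_shape)
    dcols = dcols.reshape(n, oh, ow, kh, kw, C)
    for i in range(kh):
        for j in range(kw):
            dxp[:, i:i + oh * stride:stride, j:j + ow * stride:stride, :] += \
                dcols[:, :, :, i, j, :]
    return dxp


# ---------------------------------------------------------------------------
# functional layer operations
# ---------------------------------------------------------------------------

def conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray,
                 stride: int = 1, padding: str = "same"):
    """Cross-correlate ``x`` (n,h,w,c_in) with kernels ``W`` (kh,kw,c_in,c_out).

    Returns ``(a, z, cache)`` with ``a = relu(z)`` and one bias per output
    channel; "same" padding at stride 1 preserves the spatial dimensions.
    """
    if x.ndim != 4 or W.ndim != 4 or x.shape[3] != W.shape[2]:
        raise ArchitectureError(
            f"conv shapes inconsistent: input {x.shape}, kernels {W.shape}"
        )
    kh, kw, _, oc = W.shape
    xp = _pad_same(x, kh, kw) if padding == "same" else x
    if xp.shape[1] < kh or xp.shape[2] < kw:
        raise ArchitectureError(
            f"spatial dims {xp.shape[1:3]} smaller than kernel {(kh, kw)}"
        )
    cols, oh, ow = _im2col(xp, kh, kw, stride)
    z = cols @ W.reshape(-1, oc) + b
    z = z.reshape(x.shape[0], oh, ow, oc)
    cache = {"cols": cols, "xp_shape": xp.shape, "x_shape": x.shape,
             "kh": kh, "kw": kw, "stride": stride, "padding": padding,
             "oh": oh, "ow": ow, "z": z}
    return relu(z), z, cache


def conv_backward(d_a: np.ndarray, W: np.ndarray, cache: dict):
    """Backward pass of conv+ReLU given dL/da of this layer's output.

    Returns ``(d_x, dW, db)`` where gradients are summed over the batch and
    the input error is the full correlation of delta with the rotated
    kernels (expressed via the im2col transpose).
    """
    z = cache["z"]
    dz = d_a * (z > 0)
    n, oh, ow, oc = dz.shape
    dz_flat = dz.reshape(-1, oc)
    dW = (cache["cols"].T @ dz_flat).reshape(W.shape)
    db = dz_flat.sum(axis=0)
    dcols = dz_flat @ W.reshape(-1, oc).T
    dxp = _col2im(dcols, cache["xp_shape"], cache["kh"], cache["kw"],
                  cache["stride"], oh, ow)
    if cache["padding"] == "same":
        kh, kw = cache["kh"], cache["kw"]
        pt, pl = (kh - 1) // 2, (kw - 1) // 2
        _, H, Wd, _ = cache["x_shape"]
        dx = dxp[:, pt:pt + H, pl:pl + Wd, :]
    else:
        dx = dxp
    return dx, dW, db


def max_pool_forward(x: np.ndarray, window: int = 2, stride: int = 1):
    """Valid max pooling; returns ``(out, cache)`` with argmax positions.

    Ties resolve to the first maximum in a row-major scan of the window.
    """
    n, H, W, C = x.shape
    if H < window or W < window:
        raise ArchitectureError(
            f"pool window {window} larger than input {(H, W)}"
        )
    oh = (H - window) // stride + 1
    ow = (W - window) // stride + 1
    offsets = list(product(range(window), repeat=2))  # row-major
    stack = np.stack(
        [x[:, di:di + oh * stride:stride, dj:dj + ow * stride:stride, :]
         for di, dj in offsets],
        axis=-1,
    )
    amax = stack.argmax(axis=-1)            # first max wins
    out = np.take_along_axis(stack, amax[..., None], axis=-1)[..., 0]
    cache = {"amax": amax, "x_shape": x.shape, "window": window,
             "stride": stride, "oh": oh, "ow": ow, "offsets": offsets}
    return out, cache


def pool_backward(d_out: np.ndarray, cache: dict) -> np.ndarray:
    """Route each incoming error to its recorded argmax position.

    Overlapping stride-1 windows accumulate additively, so the total error
    mass is conserved.
    """
    if d_out.shape != cache["amax"].shape:
        raise UsageError(
            f"pool cache shape {cache['amax'].shape} does not match "
            f"gradient {d_out.shape}"
        )
    dx = np.zeros(cache["x_shape"])
    oh, ow, stride = cache["oh"], cache["ow"], cache["stride"]
    for k, (di, dj) in enumerate(cache["offsets"]):
        mask = cache["amax"] == k
        dx[:, di:di + oh * stride:stride, dj:dj + ow * stride:stride, :] += \
            d_out * mask
    return dx


def dense_forward(a_prev: np.ndarray, W: np.ndarray, b: np.ndarray,
                  activation: str = "relu"):
    """Affine map ``z = W a_prev + b`` plus activation; returns ``(a, z)``."""
    if a_prev.shape[-1] != W.shape[1]:
        raise ArchitectureError(
            f"dense shapes inconsistent: input {a_prev.shape}, W {W.shape}"
        )
    z = a_prev @ W.T + b
    if activation == "relu":
        return relu(z), z
    if activation == "softmax":
        return softmax(z), z
    if activation == "linear":
        return z, z
    raise ConfigurationError(f"unknown activation {activation!r}")


def dense_backward(delta_next: np.ndarray, W_next: np.ndarray,
                   z: np.ndarray) -> np.ndarray:
    """Error of a hidden ReLU dense layer: ``(W_next^T delta_next) (.) relu'(z)``."""
    if z is None:
        raise UsageError("dense_backward needs the cached pre-activation z")
    return (delta_next @ W_next) * (z > 0)


def update_params(params: dict[str, np.ndarray],
                  grads: dict[str, np.ndarray],
                  lr: float) -> dict[str, np.ndarray]:
    """Plain gradient-descent step on batch-summed gradients (pure function)."""
    out = {}
    for name, value in params.items():
        g = grads[name]
        if not np.isfinite(g).all():
            raise DivergenceError(f"non-finite gradient for parameter {name!r}")
        out[name] = value - lr * g
    return out


# ---------------------------------------------------------------------------
# network description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    kind: str                     # input | conv | pool | flatten | dense | output
    shape: tuple = ()             # input spatial shape
    kernel: int = 3
    channels: int = 0
    stride: int = 1
    padding: str = "same"
    window: int = 2
    units: int = 0


@dataclass(frozen=True)
class NetworkSpec:
    """Ordered layer descriptors with a programmatic shape trace."""

    layers: tuple[LayerSpec, ...]

    def shape_trace(self) -> list[tuple]:
        """Per-layer output shapes, starting from the input shape."""
        trace: list[tuple] = []
        shape = None
        for layer in self.layers:
            if layer.kind == "input":
                shape = tuple(layer.shape)
            elif layer.kind == "conv":
                h, w, _ = shape
                if layer.padding == "same":
                    oh, ow = math.ceil(h / layer.stride), math.ceil(w / layer.stride)
                else:
                    oh = (h - layer.kernel) // layer.stride + 1
                    ow = (w - layer.kernel) // layer.stride + 1
                shape = (oh, ow, layer.channels)
            elif layer.kind == "pool":
                h, w, c = shape
                oh = (h - layer.window) // layer.stride + 1
                ow = (w - layer.window) // layer.stride + 1
                if oh < 1 or ow < 1:
                    raise ArchitectureError("pool window exceeds spatial dims")
                shape = (oh, ow, c)
            elif layer.kind == "flatten":
                shape = (int(np.prod(shape)),)
            elif layer.kind in ("dense", "output"):
                shape = (layer.units,)
            else:
                raise ConfigurationError(f"unknown layer kind {layer.kind!r}")
            trace.append(shape)
        return trace


def default_network_spec() -> NetworkSpec:
    """The 6x6 grid architecture used throughout the package."""
    return NetworkSpec(layers=(
        LayerSpec("input", shape=(6, 6, 1)),
        LayerSpec("conv", kernel=3, channels=32, stride=1, padding="same"),
        LayerSpec("pool", window=2, stride=1),
        LayerSpec("conv", kernel=3, channels=64, stride=1, padding="same"),
        LayerSpec("pool", window=2, stride=1),
        LayerSpec("flatten"),
        LayerSpec("dense", units=128),
        LayerSpec("dense", units=128),
        LayerSpec("output", units=2),
    ))


def mini_network_spec() -> NetworkSpec:
    """A miniature architecture small enough for finite-difference checks."""
    return NetworkSpec(layers=(
        LayerSpec("input", shape=(4, 4, 1)),
        LayerSpec("conv", kernel=3, channels=2, stride=1, padding="same"),
        LayerSpec("pool", window=2, stride=1),
        LayerSpec("flatten"),
        LayerSpec("dense", units=8),
        LayerSpec("output", units=2),
    ))


# ---------------------------------------------------------------------------
# the network object
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    max_iterations: int = 1000
    tolerance: float = 1e-6
    batch_size: int = 256
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate < 0:
            raise ConfigurationError(f"learning_rate must be >= 0, got {self.learning_rate}")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be positive")
        if self.tolerance <= 0:
            raise ConfigurationError("tolerance must be positive")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be positive")


@dataclass
class TrainingHistory:
    """Per-iteration loss and training accuracy (training-curve data)."""

    iteration: list[int] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)

    def append(self, it: int, loss: float, acc: float) -> None:
        self.iteration.append(it)
        self.loss.append(loss)
        self.accuracy.append(acc)

    def to_csv(self, path) -> None:
        lines = ["iteration,loss,accuracy"] + [
            f"{i},{l!r},{a!r}"
            for i, l, a in zip(self.iteration, self.loss, self.accuracy)
        ]
        Path(path).write_text("\n".join(lines) + "\n")


class Network:
    """Parameter container + forward/backward engine for a :class:`NetworkSpec`."""

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        self.params: dict[str, np.ndarray] = {}
        self._param_layers: list[tuple[int, LayerSpec, tuple]] = []
        trace = spec.shape_trace()
        for i, layer in enumerate(spec.layers):
            in_shape = trace[i - 1] if i > 0 else None
            if layer.kind in ("conv", "dense", "output"):
                self._param_layers.append((i, layer, in_shape))
        self._trace = trace

    # -- parameters --------------------------------------------------------
    def init_params(self, seed: int = 0) -> "Network":
        """He-uniform weights scaled by fan-in, zero biases."""
        rng = np.random.default_rng(seed)
        self.params = {}
        for i, layer, in_shape in self._param_layers:
            if layer.kind == "conv":
                kh = kw = layer.kernel
                c_in = in_shape[2]
                fan_in = kh * kw * c_in
                limit = math.sqrt(6.0 / fan_in)
                W = rng.uniform(-limit, limit, size=(kh, kw, c_in, layer.channels))
                b = np.zeros(layer.channels)
            else:
                fan_in = in_shape[0]
                limit = math.sqrt(6.0 / fan_in)
                W = rng.uniform(-limit, limit, size=(layer.units, fan_in))
                b = np.zeros(layer.units)
            self.params[f"W{i}"] = W
            self.params[f"b{i}"] = b
        return self

    def _require_params(self) -> None:
        if not self.params:
            raise UsageError("network parameters are not initialised/trained")

    def param_vector(self) -> np.ndarray:
        self._require_params()
        return np.concatenate([self.params[k].ravel() for k in sorted(self.params)])

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray, keep_cache: bool = False):
        """Full forward pass; returns output probabilities.

        With ``keep_cache`` the per-layer activations/pre-activations and
        pooling argmax positions are stored for the backward pass.
        """
        self._require_params()
        if x.ndim != 4 or x.shape[1:] != tuple(self.spec.layers[0].shape):
            raise ArchitectureError(
                f"input shape {x.shape[1:]} does not match spec "
                f"{self.spec.layers[0].shape}"
            )
        caches: list[dict] = []
        a = x
        for i, layer in enumerate(self.spec.layers):
            cache: dict = {"kind": layer.kind, "a_prev": a}
            if layer.kind == "input":
                pass
            elif layer.kind == "conv":
                a, z, conv_cache = conv_forward(
                    a, self.params[f"W{i}"], self.params[f"b{i}"],
                    stride=layer.stride, padding=layer.padding,
                )
                cache.update(conv=conv_cache, z=z)
            elif layer.kind == "pool":
                a, pool_cache = max_pool_forward(a, layer.window, layer.stride)
                cache.update(pool=pool_cache)
            elif layer.kind == "flatten":
                cache.update(in_shape=a.shape)
                a = a.reshape(a.shape[0], -1)
            elif layer.kind == "dense":
                a, z = dense_forward(a, self.params[f"W{i}"], self.params[f"b{i}"],
                                     activation="relu")
                cache.update(z=z)
            elif layer.kind == "output":
                a, z = dense_forward(a, self.params[f"W{i}"], self.params[f"b{i}"],
                                     activation="softmax")
                cache.update(z=z)
            cache["a"] = a
            caches.append(cache)
        if keep_cache:
            self._caches = caches
        return a

    # -- backward ----------------------------------------------------------
    def backward(self, y_onehot: np.ndarray) -> dict[str, np.ndarray]:
        """Batch-summed gradients of the total cross-entropy (uses last forward)."""
        if not hasattr(self, "_caches"):
            raise UsageError("call forward(..., keep_cache=True) before backward")
        caches = self._caches
        grads: dict[str, np.ndarray] = {}
        delta = None                     # dL/da of the downstream layer
        for i in range(len(self.spec.layers) - 1, 0, -1):
            layer = self.spec.layers[i]
            cache = caches[i]
            if layer.kind == "output":
                dz = cache["a"] - y_onehot               # softmax + CE
                grads[f"W{i}"] = dz.T @ cache["a_prev"]
                grads[f"b{i}"] = dz.sum(axis=0)
                delta = dz @ self.params[f"W{i}"]
            elif layer.kind == "dense":
                dz = delta * (cache["z"] > 0)
                grads[f"W{i}"] = dz.T @ cache["a_prev"]
                grads[f"b{i}"] = dz.sum(axis=0)
                delta = dz @ self.params[f"W{i}"]
            elif layer.kind == "flatten":
                delta = delta.reshape(cache["in_shape"])
            elif layer.kind == "pool":
                delta = pool_backward(delta, cache["pool"])
            elif layer.kind == "conv":
                delta, dW, db = conv_backward(delta, self.params[f"W{i}"],
                                              cache["conv"])
                grads[f"W{i}"] = dW
                grads[f"b{i}"] = db
        return grads

    # -- hidden features ---------------------------------------------------
    def penultimate_features(self, x: np.ndarray) -> np.ndarray:
        """Activations of the last dense layer before the output layer."""
        self._require_params()
        a = x
        last_dense = max(i for i, l in enumerate(self.spec.layers)
                         if l.kind == "dense")
        for i, layer in enumerate(self.spec.layers):
            if layer.kind == "conv":
                a, _, _ = conv_forward(a, self.params[f"W{i}"], self.params[f"b{i}"],
                                       stride=layer.stride, padding=layer.padding)
            elif layer.kind == "pool":
                a, _ = max_pool_forward(a, layer.window, layer.stride)
            elif layer.kind == "flatten":
                a = a.reshape(a.shape[0], -1)
            elif layer.kind == "dense":
                a, _ = dense_forward(a, self.params[f"W{i}"], self.params[f"b{i}"],
                                     activation="relu")
            if i == last_dense:
                return a
        raise ArchitectureError("spec has no dense layer before the output")

    # -- serialisation -----------------------------------------------------
    def save(self, archive_path, sidecar_path=None) -> None:
        self._require_params()
        np.savez(archive_path, **self.params)
        if sidecar_path is not None:
            spec_json = [vars(l) | {"shape": list(l.shape)} for l in self.spec.layers]
            Path(sidecar_path).write_text(json.dumps(spec_json, indent=1))

    @classmethod
    def load(cls, spec: NetworkSpec, archive_path) -> "Network":
        net = cls(spec)
        with np.load(archive_path) as data:
            net.params = {k: data[k] for k in data.files}
        return net


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------

def train_network(
    spec: NetworkSpec,
    grids: np.ndarray,
    y_onehot: np.ndarray,
    config: TrainConfig,
) -> tuple[Network, TrainingHistory]:
    """Gradient-descent training loop with a parameter-change stopping rule.

    Each iteration draws one batch of ``min(n, batch_size)`` rows (the whole
    set when it fits), runs forward/backward, and applies the summed-gradient
    update.  The loop stops when the Frobenius norm of the concatenated
    parameter change drops below ``tolerance`` or after ``max_iterations``.
    """
    config.validate()
    n = len(grids)
    if y_onehot.shape != (n, 2):
        raise ConfigurationError(
            f"labels must be one-hot over 2 classes, got {y_onehot.shape}"
        )
    net = Network(spec).init_params(seed=config.seed)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    m = min(n, config.batch_size)
    history = TrainingHistory()
    for t in range(1, config.max_iterations + 1):
        batch = np.arange(n) if m == n else rng.choice(n, size=m, replace=False)
        xb, yb = grids[batch], y_onehot[batch]
        probs = net.forward(xb, keep_cache=True)
        loss = cross_entropy(probs, yb)
        if not np.isfinite(loss):
            raise DivergenceError(f"non-finite loss at iteration {t}")
        acc = float(np.mean(probs.argmax(axis=1) == yb.argmax(axis=1)))
        history.append(t, loss, acc)
        grads = net.backward(yb)
        new_params = update_params(net.params, grads, config.learning_rate)
        delta_norm = math.sqrt(sum(
            float(np.sum((new_params[k] - net.params[k]) ** 2))
            for k in net.params
        ))
        net.params = new_params
        if delta_norm < config.tolerance:
            break
    return net, history


def extract_features(net: Network, grids: np.ndarray) -> np.ndarray:
    """Last-dense-layer activations: the ``n x 128`` representation used by bagging."""
    return net.penultimate_features(grids)


def predict_softmax(net: Network, grids: np.ndarray):
    """Class labels (argmax; ties to class 0) and per-row class probabilities."""
    probs = net.forward(grids)
    return probs.argmax(axis=1), probs


# ---------------------------------------------------------------------------
# gradient checking
# ---------------------------------------------------------------------------

def gradient_check(
    spec: NetworkSpec | None = None,
    seed: int = 0,
    n_samples: int = 3,
    step: float = 1e-5,
) -> float:
    """Max relative error between analytic and central-difference gradients.

    The loss is the total (batch-summed) cross-entropy of a random batch, so
    the analytic batch-summed gradients are exactly its derivative.  Relative
    error uses ``|ga - gn| / max(|ga|, |gn|, 1e-4)`` — the floor keeps dead
    ReLU units (both gradients ~ 0) from inflating the ratio.
    """
    if spec is None:
        spec = mini_network_spec()
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_samples,) + tuple(spec.layers[0].shape))
    y_idx = rng.integers(0, 2, size=n_samples)
    y = np.eye(2)[y_idx]
    net = Network(spec).init_params(seed=seed + 1)

    def total_loss() -> float:
        probs = net.forward(x)
        return cross_entropy(probs, y) * n_samples   # summed CE

    net.forward(x, keep_cache=True)
    grads = net.backward(y)

    worst = 0.0
    for name in sorted(net.params):
        W = net.params[name]
        g = grads[name]
        it = np.nditer(W, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = W[idx]
            W[idx] = orig + step
            up = total_loss()
            W[idx] = orig - step
            down = total_loss()
            W[idx] = orig
            gn = (up - down) / (2 * step)
            ga = g[idx]
            rel = abs(ga - gn) / max(abs(ga), abs(gn), 1e-4)
            worst = max(worst, rel)
    return worst
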