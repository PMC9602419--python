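"""Attention-augmented convolutional classifier, in pure numpy.

The classifier is a five-block CNN for binary pneumonia recognition:
each block is conv(3x3, same) -> batch norm -> LeakyReLU -> CBAM ->
max-pool(2x2), with dropout after blocks 2, 4 and 5, followed by a
flatten -> fully-connected -> LeakyReLU -> fully-connected -> sigmoid
head.  Training minimises binary cross-entropy with the Adam optimiser
under a continuous exponential-decay learning-rate schedule

    lr(t) = lr0 * decay_rate ** (t / decay_steps).

Everything — forward passes, backpropagation, Adam — is implemented
here on float64 numpy arrays.  Each vectorised op has a brute-force
loop oracle in the test-suite, and the composite blocks are verified by
numerical differentiation, so the implementation doubles as a reference.

Layout convention: batched feature maps are ``(B, C, H, W)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "conv2d",
    "leaky_relu",
    "max_pool",
    "binary_cross_entropy",
    "LrSchedule",
    "decayed_learning_rate",
    "AdamState",
    "adam_step",
    "NetworkSpec",
    "TrainConfig",
    "Model",
    "build_network",
    "train",
    "evaluate",
]

_EPS_PROB = 1e-12


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if x.dtype not in (np.float32, np.float64):
        x = x.astype(float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def conv2d(
    x: np.ndarray,
    kernel: np.ndarray,
    bias: Optional[np.ndarray] = None,
    mode: str = "same",
) -> np.ndarray:
    """2-D multichannel correlation.

    ``x`` is ``(C_in, H, W)``, ``kernel`` is ``(C_out, C_in, k, k)``,
    ``bias`` is ``(C_out,)``.  ``mode='same'`` zero-pads to preserve the
    spatial size; ``mode='valid'`` returns ``(H-k+1, W-k+1)`` maps, the
    classic output-size convention for an m x m input and n x n kernel.
    """
    x = np.asarray(x, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if x.ndim != 3 or kernel.ndim != 4:
        raise ValueError("x must be (C,H,W) and kernel (C_out,C_in,k,k)")
    if x.shape[0] != kernel.shape[1]:
        raise ValueError("channel count mismatch between input and kernel")
    k = kernel.shape[2]
    if mode == "same":
        p = k // 2
        x = np.pad(x, ((0, 0), (p, p), (p, p)))
    elif mode != "valid":
        raise ValueError("mode must be 'same' or 'valid'")
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    out = np.einsum("chwij,ocij->ohw", win, kernel)
    if bias is not None:
        out += np.asarray(bias, dtype=float)[:, None, None]
    return out


def leaky_relu(x, a: float = 0.01):
    """LeakyReLU activation: ``x`` for ``x > 0``, else ``a * x``."""
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, x, a * x)


def max_pool(x: np.ndarray, r: int = 2) -> np.ndarray:
    """Per-channel block maxima with an ``r x r`` window and stride ``r``.

    Trailing rows/columns that do not fill a window are dropped.
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    c, h, w = x.shape
    ho, wo = h // r, w // r
    xr = x[:, : ho * r, : wo * r].reshape(c, ho, r, wo, r)
    out = xr.max(axis=(2, 4))
    return out[0] if squeeze else out


def binary_cross_entropy(y: np.ndarray, p: np.ndarray) -> float:
    """Mean negative log-likelihood of binary labels under probabilities p."""
    y = np.asarray(y, dtype=float).ravel()
    p = np.asarray(p, dtype=float).ravel()
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have the same length")
    p = np.clip(p, _EPS_PROB, 1.0 - _EPS_PROB)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


@dataclass
class LrSchedule:
    """Continuous exponential-decay learning-rate schedule."""

    learning_rate: float = 1e-4
    decay_rate: float = 0.96
    decay_steps: int = 100
    global_step: int = 0


def decayed_learning_rate(s: LrSchedule, global_step: Optional[int] = None) -> float:
    """``lr0 * decay_rate ** (global_step / decay_steps)`` (non-staircase)."""
    step = s.global_step if global_step is None else global_step
    return s.learning_rate * s.decay_rate ** (step / s.decay_steps)


@dataclass
class AdamState:
    """State of the Adam optimiser for one parameter vector."""

    theta: np.ndarray
    m: Optional[np.ndarray] = None
    v: Optional[np.ndarray] = None
    t: int = 0
    alpha: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.m is None:
            self.m = np.zeros_like(self.theta)
        if self.v is None:
            self.v = np.zeros_like(self.theta)


def adam_step(state: AdamState, g: np.ndarray) -> AdamState:
    """One Adam update with bias-corrected moment estimates (pure function)."""
    g = np.asarray(g, dtype=float)
    t = state.t + 1
    m = state.beta1 * state.m + (1.0 - state.beta1) * g
    v = state.beta2 * state.v + (1.0 - state.beta2) * g**2
    m_hat = m / (1.0 - state.beta1**t)
    v_hat = v / (1.0 - state.beta2**t)
    theta = state.theta - state.alpha * m_hat / (np.sqrt(v_hat) + state.eps)
    return replace(state, theta=theta, m=m, v=v, t=t)


# ---------------------------------------------------------------------------
# differentiable layers
# ---------------------------------------------------------------------------

class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "", dtype=np.float64):
        self.value = np.asarray(value, dtype=dtype)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B,C,H,W) -> (B*H*W, C*k*k) patch matrix for stride-1 correlation."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    b, c, h, w = win.shape[:4]
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * k * k), (b, h, w, c)


def _col2im(dcols: np.ndarray, dims, k: int, pad: int, hw: Tuple[int, int]) -> np.ndarray:
    b, h, w, c = dims
    dcols = dcols.reshape(b, h, w, c, k, k)
    hp, wp = hw[0] + 2 * pad, hw[1] + 2 * pad
    dxp = np.zeros((b, c, hp, wp), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2dLayer(Layer):
    """Same-padded stride-1 convolution block layer."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 name="", dtype=np.float64):
        scale = math.sqrt(2.0 / (c_in * k * k))
        self.w = Param(rng.normal(0, scale, (c_out, c_in, k, k)), f"{name}.w", dtype)
        self.b = Param(np.zeros(c_out), f"{name}.b", dtype)
        self.k = k

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        self._hw = x.shape[2:]
        cols, self._dims = _im2col(x, self.k, self.k // 2)
        self._cols = cols
        c_out = self.w.value.shape[0]
        out = cols @ self.w.value.reshape(c_out, -1).T + self.b.value
        b, h, w, _ = self._dims
        return out.reshape(b, h, w, c_out).transpose(0, 3, 1, 2)

    def backward(self, dout):
        b, h, w, _ = self._dims
        c_out = dout.shape[1]
        dmat = dout.transpose(0, 2, 3, 1).reshape(-1, c_out)
        self.w.grad += (dmat.T @ self._cols).reshape(self.w.value.shape)
        self.b.grad += dmat.sum(axis=0)
        dcols = dmat @ self.w.value.reshape(c_out, -1)
        return _col2im(dcols, self._dims, self.k, self.k // 2, self._hw)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5,
                 name="", dtype=np.float64):
        self.gamma = Param(np.ones(c), f"{name}.gamma", dtype)
        self.beta = Param(np.zeros(c), f"{name}.beta", dtype)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            dt = self.running_mean.dtype
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu).astype(dt)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(dt)
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mu[:, None, None]) / std[:, None, None]
        self._cache = (xhat, std, train, x.shape)
        return self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]

    def backward(self, dout):
        xhat, std, was_train, shape = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.value[:, None, None]
        if not was_train:
            return dout * g / std[:, None, None]
        n = shape[0] * shape[2] * shape[3]
        dxhat = dout * g
        return (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) / std[:, None, None]


class LeakyReLULayer(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class MaxPool2d(Layer):
    def __init__(self, r: int = 2):
        self.r = r

    def forward(self, x, train):
        r = self.r
        b, c, h, w = x.shape
        ho, wo = h // r, w // r
        self._in_shape = x.shape
        xr = x[:, :, : ho * r, : wo * r].reshape(b, c, ho, r, wo, r)
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, ho, wo, r * r)
        self._idx = flat.argmax(axis=-1)
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        r = self.r
        b, c, h, w = self._in_shape
        ho, wo = h // r, w // r
        dflat = np.zeros((b, c, ho, wo, r * r), dtype=dout.dtype)
        np.put_along_axis(dflat, self._idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros((b, c, h, w), dtype=dout.dtype)
        dx[:, :, : ho * r, : wo * r] = (
            dflat.reshape(b, c, ho, wo, r, r).transpose(0, 1, 2, 4, 3, 5).reshape(
                b, c, ho * r, wo * r
            )
        )
        return dx


class Dropout(Layer):
    """Inverted dropout; active only when training."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.p) / (1.0 - self.p)).astype(x.dtype)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class CBAMBlock(Layer):
    """Differentiable CBAM: channel then spatial attention (see attention.py)."""

    def __init__(self, c: int, reduction: int, kernel: int, rng, name="", dtype=np.float64):
        hidden = max(1, c // reduction)
        self.w1 = Param(rng.normal(0, math.sqrt(2.0 / c), (c, hidden)), f"{name}.w1", dtype)
        self.w2 = Param(rng.normal(0, math.sqrt(2.0 / hidden), (hidden, c)), f"{name}.w2", dtype)
        self.b2 = Param(np.zeros(c), f"{name}.b2", dtype)
        self.cw = Param(
            rng.normal(0, math.sqrt(2.0 / (2 * kernel * kernel)), (1, 2, kernel, kernel)),
            f"{name}.cw", dtype,
        )
        self.cb = Param(np.zeros(1), f"{name}.cb", dtype)
        self.kernel = kernel

    def params(self):
        return [self.w1, self.w2, self.b2, self.cw, self.cb]

    def forward(self, x, train):
        b, c, h, w = x.shape
        avg = x.mean(axis=(2, 3))
        mx_idx = x.reshape(b, c, -1).argmax(axis=-1)
        mx = np.take_along_axis(x.reshape(b, c, -1), mx_idx[..., None], axis=-1)[..., 0]
        ha = np.maximum(0.0, avg @ self.w1.value)
        hm = np.maximum(0.0, mx @ self.w1.value)
        s = _sigmoid((ha + hm) @ self.w2.value + 2.0 * self.b2.value)
        x1 = x * s[:, :, None, None]
        ca = x1.mean(axis=1)
        cidx = x1.argmax(axis=1)
        cm = np.take_along_axis(x1, cidx[:, None], axis=1)[:, 0]
        u = np.stack([ca, cm], axis=1)
        cols, dims = _im2col(u, self.kernel, self.kernel // 2)
        z = (cols @ self.cw.value.reshape(1, -1).T + self.cb.value).reshape(b, h, w)
        t = _sigmoid(z)[:, None]
        self._cache = (x, avg, mx_idx, mx, ha, hm, s, x1, cidx, u, cols, dims, t)
        return x1 * t

    def backward(self, dout):
        x, avg, mx_idx, mx, ha, hm, s, x1, cidx, u, cols, dims, t = self._cache
        b, c, h, w = x.shape
        # spatial stage
        dt = (dout * x1).sum(axis=1, keepdims=True)
        dx1 = dout * t
        dz = (dt * t * (1.0 - t))[:, 0]
        dmat = dz.reshape(-1, 1)
        self.cw.grad += (dmat.T @ cols).reshape(self.cw.value.shape)
        self.cb.grad += dmat.sum(axis=0)
        dcols = dmat @ self.cw.value.reshape(1, -1)
        du = _col2im(dcols, dims, self.kernel, self.kernel // 2, (h, w))
        dx1 += du[:, 0][:, None] / c
        np.put_along_axis(
            dx1,
            cidx[:, None],
            np.take_along_axis(dx1, cidx[:, None], axis=1) + du[:, 1][:, None],
            axis=1,
        )
        # channel stage
        ds = (dx1 * x).sum(axis=(2, 3))
        dx = dx1 * s[:, :, None, None]
        dls = ds * s * (1.0 - s)
        dsum = dls @ self.w2.value.T
        self.w2.grad += (ha + hm).T @ dls
        self.b2.grad += 2.0 * dls.sum(axis=0)
        da = dsum * (ha > 0)
        dm = dsum * (hm > 0)
        self.w1.grad += avg.T @ da + mx.T @ dm
        davg = da @ self.w1.value.T
        dmx = dm @ self.w1.value.T
        dx += davg[:, :, None, None] / (h * w)
        dxf = dx.reshape(b, c, -1)
        np.put_along_axis(
            dxf,
            mx_idx[..., None],
            np.take_along_axis(dxf, mx_idx[..., None], axis=-1) + dmx[..., None],
            axis=-1,
        )
        return dxf.reshape(b, c, h, w)


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng, name="", dtype=np.float64):
        self.w = Param(rng.normal(0, math.sqrt(2.0 / n_in), (n_in, n_out)), f"{name}.w", dtype)
        self.b = Param(np.zeros(n_out), f"{name}.b", dtype)

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout):
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T


# ---------------------------------------------------------------------------
# the classifier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of the five-block attention CNN.

    ``channels`` are the conv widths of the five blocks; dropout is
    applied after the blocks listed in ``dropout_after`` (1-based).
    """

    input_size: int = 224
    channels: Tuple[int, ...] = (16, 32, 64, 128, 128)
    fc_hidden: int = 64
    leaky_slope: float = 0.01
    dropout_rate: float = 0.3
    dropout_after: Tuple[int, ...] = (2, 4, 5)
    reduction_ratio: int = 16
    spatial_kernel: int = 7

    def __post_init__(self) -> None:
        if len(self.channels) != 5:
            raise ValueError("exactly five conv blocks are required")
        if self.input_size < 32:
            raise ValueError("input_size must be >= 32 to survive five poolings")

    @property
    def feature_side(self) -> int:
        side = self.input_size
        for _ in range(5):
            side //= 2
        return side


class Model:
    """Sequential five-block CBAM-CNN with a sigmoid binary head.

    ``dtype=np.float32`` (the default) is plenty for training and about
    twice as fast as float64; pass ``np.float64`` when verifying
    gradients numerically.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence(seed).spawn(1)[0]
        )
        layers: List[Layer] = []
        c_prev = 1
        for i, c in enumerate(spec.channels, start=1):
            layers.append(Conv2dLayer(c_prev, c, 3, rng, name=f"block{i}.conv", dtype=dtype))
            layers.append(BatchNorm2d(c, name=f"block{i}.bn", dtype=dtype))
            layers.append(LeakyReLULayer(spec.leaky_slope))
            layers.append(
                CBAMBlock(c, spec.reduction_ratio, spec.spatial_kernel, rng,
                          name=f"block{i}.cbam", dtype=dtype)
            )
            layers.append(MaxPool2d(2))
            if i in spec.dropout_after:
                layers.append(Dropout(spec.dropout_rate, self._dropout_rng))
            c_prev = c
        side = spec.feature_side
        layers.append(Flatten())
        layers.append(Linear(c_prev * side * side, spec.fc_hidden, rng, name="fc1", dtype=dtype))
        layers.append(LeakyReLULayer(spec.leaky_slope))
        layers.append(Linear(spec.fc_hidden, 1, rng, name="fc2", dtype=dtype))
        self.layers = layers

    def params(self) -> List[Param]:
        out: List[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch ``(B, 1, H, W)``."""
        x = np.asarray(x, dtype=self.dtype)
        for layer in self.layers:
            x = layer.forward(x, train)
        return x[:, 0].astype(float)

    def backward(self, dlogits: np.ndarray) -> None:
        d = np.asarray(dlogits, dtype=self.dtype)[:, None]
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_proba(self, images: Sequence, batch_size: int = 64) -> np.ndarray:
        """Class-1 probabilities, evaluation mode (dropout off, BN running stats)."""
        x = _stack_pixels(images)
        out = []
        for i in range(0, len(x), batch_size):
            out.append(_sigmoid(self.forward(x[i : i + batch_size], train=False)))
        return np.concatenate(out) if out else np.empty(0)

    # -- checkpointing --------------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {p.name: p.value for p in self.params()}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm2d):
                state[f"bn{i}.running_mean"] = layer.running_mean
                state[f"bn{i}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = state[p.name]
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm2d):
                dt = layer.gamma.value.dtype
                layer.running_mean = np.asarray(state[f"bn{i}.running_mean"], dtype=dt)
                layer.running_var = np.asarray(state[f"bn{i}.running_var"], dtype=dt)


def build_network(spec: NetworkSpec, seed: int = 0, dtype=np.float32) -> Model:
    """Construct the five conv / five pool / one-FC-output classifier."""
    return Model(spec, seed=seed, dtype=dtype)


def _stack_pixels(images: Sequence) -> np.ndarray:
    arrs = [im.pixels if hasattr(im, "pixels") else np.asarray(im) for im in images]
    return np.stack(arrs)[:, None, :, :].astype(float)


def _labels_of(images: Sequence) -> np.ndarray:
    return np.array([im.label for im in images], dtype=float)


@dataclass
class TrainConfig:
    """Optimiser and schedule hyper-parameters.

    ``decay_steps=None`` uses one epoch's step count, so the learning
    rate decays by ``decay_rate`` per epoch.  ``target_accuracy`` stops
    training early once the monitored (validation if given, else
    training) accuracy reaches it.
    """

    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 1e-4
    decay_rate: float = 0.96
    decay_steps: Optional[int] = None
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0
    target_accuracy: Optional[float] = None


class _AdamOpt:
    def __init__(self, params: List[Param], cfg: TrainConfig):
        self.params = params
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0
        self.cfg = cfg

    def step(self, lr: float) -> None:
        c = self.cfg
        self.t += 1
        bc1 = 1.0 - c.beta1**self.t
        bc2 = 1.0 - c.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= c.beta1
            m += (1 - c.beta1) * p.grad
            v *= c.beta2
            v += (1 - c.beta2) * p.grad**2
            p.value -= lr * (m / bc1) / (np.sqrt(v / bc2) + c.eps)


def train(
    model: Model,
    train_set: Sequence,
    config: TrainConfig,
    val_set: Optional[Sequence] = None,
) -> Dict[str, list]:
    """Train by Adam on binary cross-entropy; returns the epoch history.

    History keys: ``epoch``, ``lr``, ``train_loss``, ``train_accuracy``
    and, when a validation set is given, ``val_loss`` /
    ``val_accuracy``.  Dropout and batch-norm statistics are active only
    during the optimisation passes; the logged metrics are computed in
    evaluation mode.  Deterministic for a fixed seed.
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    x = _stack_pixels(train_set)
    y = _labels_of(train_set)
    n = len(train_set)
    steps_per_epoch = max(1, math.ceil(n / config.batch_size))
    schedule = LrSchedule(
        learning_rate=config.learning_rate,
        decay_rate=config.decay_rate,
        decay_steps=config.decay_steps or steps_per_epoch,
    )
    opt = _AdamOpt(model.params(), config)
    shuffle_rng = np.random.default_rng(config.seed)

    history: Dict[str, list] = {k: [] for k in ("epoch", "lr", "train_loss", "train_accuracy")}
    if val_set is not None:
        history["val_loss"] = []
        history["val_accuracy"] = []

    global_step = 0
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        batch_losses, batch_hits, batch_sizes = [], [], []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.forward(xb, train=True)
            p = _sigmoid(logits)
            model.zero_grad()
            model.backward((p - yb) / len(yb))
            lr = decayed_learning_rate(schedule, global_step)
            opt.step(lr)
            global_step += 1
            batch_losses.append(binary_cross_entropy(yb, p) * len(yb))
            batch_hits.append(float(np.sum((p >= 0.5) == (yb == 1))))
            batch_sizes.append(len(yb))

        history["epoch"].append(epoch)
        history["lr"].append(decayed_learning_rate(schedule, epoch * steps_per_epoch))
        history["train_loss"].append(sum(batch_losses) / n)
        history["train_accuracy"].append(sum(batch_hits) / n)
        monitored = history["train_accuracy"][-1]
        if val_set is not None:
            va_p = model.predict_proba(val_set)
            va_y = _labels_of(val_set)
            history["val_loss"].append(binary_cross_entropy(va_y, va_p))
            history["val_accuracy"].append(float(np.mean((va_p >= 0.5) == (va_y == 1))))
            monitored = history["val_accuracy"][-1]
        if config.target_accuracy is not None and monitored >= config.target_accuracy:
            break
    return history


def evaluate(model: Model, dataset: Sequence) -> float:
    """Fraction of samples whose thresholded probability matches the label."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    p = model.predict_proba(dataset)
    y = _labels_of(dataset)
    return float(np.mean((p >= 0.5) == (y == 1)))
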