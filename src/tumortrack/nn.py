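"""Minimal 1-D convolutional network engine (numpy, manual backprop).

Supports exactly what the tracking CNN needs: 1-D convolutions (im2col),
batch normalization, inverted dropout, dense layers, ReLU, Adam, and mean
absolute error.  Everything is deterministic given the seeds handed to the
constructors and the training loop; there is no threading or stochastic
kernel dispatch, so identical runs produce identical parameter
trajectories to the last bit.

Array convention: activations are ``(batch, channels, length)`` until the
flatten layer, ``(batch, features)`` after.
"""

from __future__ import annotations

import numpy as np


class Layer:
    kind = "layer"
    trainable: bool = False

    def parameters(self) -> list[np.ndarray]:
        return []

    def gradients(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _relu(x):
    return np.maximum(x, 0.0)


class Conv1D(Layer):
    """Same-padded strided 1-D convolution with optional ReLU."""

    kind = "conv"
    trainable = True

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 activation: str | None = "relu", rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        # He initialization for ReLU stacks
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.w = rng.normal(0.0, scale, (c_out, c_in, kernel))
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.stride = int(stride)
        self.kernel = int(kernel)
        self.activation = activation
        self._cache = None

    def parameters(self):
        return [self.w, self.b]

    def gradients(self):
        return [self.dw, self.db]

    def _indices(self, length: int):
        k, s = self.kernel, self.stride
        l_out = -(-length // s)  # ceil
        pad_total = max((l_out - 1) * s + k - length, 0)
        pad_l = pad_total // 2
        starts = np.arange(l_out) * s
        idx = starts[:, None] + np.arange(k)[None, :]  # (l_out, k) into padded axis
        return l_out, pad_l, pad_total - pad_l, idx

    def forward(self, x, training):
        n, c, length = x.shape
        k = self.kernel
        l_out, pl, pr, idx = self._indices(length)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        # im2col: (n * l_out, c * k) rows against a (c_out, c * k) kernel
        cols = (
            xp[:, :, idx].transpose(0, 2, 1, 3).reshape(n * l_out, c * k)
        )
        pre = (
            (cols @ self.w.reshape(-1, c * k).T)
            .reshape(n, l_out, -1)
            .transpose(0, 2, 1)
        ) + self.b[None, :, None]
        y = _relu(pre) if self.activation == "relu" else pre
        self._cache = (cols, pre, x.shape, pl, idx)
        return y

    def backward(self, dy):
        cols, pre, x_shape, pl, idx = self._cache
        if self.activation == "relu":
            dy = dy * (pre > 0)
        n, c, length = x_shape
        k = self.kernel
        l_out = dy.shape[2]
        dyt = dy.transpose(0, 2, 1).reshape(n * l_out, -1)  # (n*l_out, c_out)
        self.dw[...] = (dyt.T @ cols).reshape(self.w.shape)
        self.db[...] = dyt.sum(axis=0)
        dcols = (dyt @ self.w.reshape(-1, c * k)).reshape(n, l_out, c, k)
        dpatches = dcols.transpose(0, 2, 1, 3)  # (n, c, l_out, k)
        lp_full = max(pl + length, int(idx.max()) + 1)
        dxp = np.zeros((n, c, lp_full))
        np.add.at(dxp, (slice(None), slice(None), idx), dpatches)
        return dxp[:, :, pl : pl + length]


class BatchNorm(Layer):
    """Per-channel batch normalization for (n, c, l) or (n, f) inputs."""

    kind = "batchnorm"
    trainable = True

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        #: frozen batch-norm normalizes with running statistics even while
        #: training (small-batch fine-tuning would otherwise corrupt them)
        self.frozen = False
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def gradients(self):
        return [self.dgamma, self.dbeta]

    @staticmethod
    def _axes(x):
        return (0, 2) if x.ndim == 3 else (0,)

    def _shape(self, x, v):
        return v[None, :, None] if x.ndim == 3 else v[None, :]

    def forward(self, x, training):
        axes = self._axes(x)
        batch_stats = training and not self.frozen
        if batch_stats:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean *= self.momentum
            self.running_mean += (1 - self.momentum) * mean
            self.running_var *= self.momentum
            self.running_var += (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._shape(x, mean)) * self._shape(x, inv)
        self._cache = (xhat, inv, axes, x.shape, batch_stats)
        return self._shape(x, self.gamma) * xhat + self._shape(x, self.beta)

    def backward(self, dy):
        xhat, inv, axes, shape, batch_stats = self._cache
        self.dgamma[...] = (dy * xhat).sum(axis=axes)
        self.dbeta[...] = dy.sum(axis=axes)
        g = self._shape(dy, self.gamma) * self._shape(dy, inv)
        if not batch_stats:  # running stats are constants w.r.t. the batch
            return g * dy
        term = dy - dy.mean(axis=axes, keepdims=True) - xhat * (dy * xhat).mean(
            axis=axes, keepdims=True
        )
        return g * term


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time and at rate 0."""

    kind = "dropout"

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()
        self._mask = None

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    kind = "flatten"

    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    kind = "dense"
    trainable = True

    def __init__(self, n_in: int, n_out: int, activation: str | None = None,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / n_in) if activation == "relu" else np.sqrt(1.0 / n_in)
        self.w = rng.normal(0.0, scale, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.activation = activation
        self._cache = None

    def parameters(self):
        return [self.w, self.b]

    def gradients(self):
        return [self.dw, self.db]

    def forward(self, x, training):
        pre = x @ self.w + self.b
        y = _relu(pre) if self.activation == "relu" else pre
        self._cache = (x, pre)
        return y

    def backward(self, dy):
        x, pre = self._cache
        if self.activation == "relu":
            dy = dy * (pre > 0)
        self.dw[...] = x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.w.T


class Sequential:
    """A plain layer stack with joint forward/backward passes."""

    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.parameters()]

    def gradients(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.gradients()]

    def state_arrays(self) -> list[np.ndarray]:
        """All persistent state: parameters plus batch-norm running stats."""
        out = list(self.parameters())
        for l in self.layers:
            if isinstance(l, BatchNorm):
                out.extend([l.running_mean, l.running_var])
        return out

    def set_state(self, arrays: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError("state array count mismatch")
        for dst, src in zip(own, arrays):
            if dst.shape != src.shape:
                raise ValueError("state array shape mismatch")
            dst[...] = src

    def census(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for l in self.layers:
            out[l.kind] = out.get(l.kind, 0) + 1
        return out

    def copy(self) -> "Sequential":
        import copy

        return copy.deepcopy(self)


class Adam:
    """Adam optimizer over a parameter list; learning rate set per step."""

    def __init__(self, params: list[np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def mae_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its gradient with respect to ``pred``."""
    diff = pred - target
    loss = float(np.mean(np.abs(diff)))
    grad = np.sign(diff) / diff.size
    return loss, grad
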