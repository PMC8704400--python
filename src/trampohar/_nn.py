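"""Minimal 1D-CNN engine in numpy: layers, Adam, and minibatch training.

Supports exactly the architecture family the package needs — Conv1D with
same-padding and ReLU, MaxPool1D, global average pooling, Flatten, Dense —
trained with softmax / categorical cross-entropy and Adam.  Everything is
float32 and fully deterministic given a seed (Glorot-uniform initialization
drawn from a single `numpy.random.Generator`, in-order minibatch shuffling),
so repeated runs reproduce identical weights bit for bit.

Shapes: sequence tensors are (batch, length, channels); dense inputs are
(batch, features).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv1D", "MaxPool1D", "GlobalAvgPool1D", "Flatten", "Dense",
           "SequentialNet", "softmax"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def init(self, rng: np.random.Generator) -> None:  # pragma: no cover - trivial
        pass

    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        raise NotImplementedError


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv1D(_Layer):
    """Same-padding 1D convolution (stride 1) with optional ReLU."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, relu: bool = True):
        super().__init__()
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.relu = relu
        self.w = np.zeros((kernel * in_ch, out_ch), np.float32)
        self.b = np.zeros(out_ch, np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def init(self, rng: np.random.Generator) -> None:
        self.w[...] = _glorot(
            rng, self.w.shape, self.kernel * self.in_ch, self.kernel * self.out_ch
        )
        self.b[...] = 0.0

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        b, l, c = x.shape
        pl, pr = (self.kernel - 1) // 2, self.kernel // 2
        xp = np.zeros((b, l + pl + pr, c), np.float32)
        xp[:, pl : pl + l] = x
        self._pad = (pl, pr, l)
        return np.concatenate(
            [xp[:, i : i + l] for i in range(self.kernel)], axis=2
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols = self._im2col(x)                     # (B, L, K*C)
        self._cols = cols
        y = cols @ self.w + self.b
        if self.relu:
            self._mask = y > 0
            y *= self._mask
        return y

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        if self.relu:
            dy = dy * self._mask
        b, l, _ = dy.shape
        cols2d = self._cols.reshape(b * l, -1)
        dy2d = dy.reshape(b * l, -1)
        self.grads[0][...] = cols2d.T @ dy2d
        self.grads[1][...] = dy2d.sum(axis=0)
        if not need_dx:
            return None
        dcols = dy @ self.w.T                      # (B, L, K*C)
        pl, pr, _ = self._pad
        dxp = np.zeros((b, l + pl + pr, self.in_ch), np.float32)
        for i in range(self.kernel):
            dxp[:, i : i + l] += dcols[:, :, i * self.in_ch : (i + 1) * self.in_ch]
        return dxp[:, pl : pl + l]


class MaxPool1D(_Layer):
    """Non-overlapping max pooling; an odd trailing sample is dropped."""

    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, l, c = x.shape
        lo = l // self.pool
        xr = x[:, : lo * self.pool].reshape(b, lo, self.pool, c)
        self._idx = xr.argmax(axis=2)
        self._in_shape = (b, l, c)
        return np.take_along_axis(xr, self._idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        if not need_dx:
            return None
        b, l, c = self._in_shape
        lo = l // self.pool
        dxr = np.zeros((b, lo, self.pool, c), np.float32)
        np.put_along_axis(dxr, self._idx[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((b, l, c), np.float32)
        dx[:, : lo * self.pool] = dxr.reshape(b, lo * self.pool, c)
        return dx


class GlobalAvgPool1D(_Layer):
    """Average each channel over the sequence: (B, L, C) -> (B, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._l = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        if not need_dx:
            return None
        return np.repeat(dy[:, None, :] / self._l, self._l, axis=1).astype(np.float32)


class Flatten(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        if not need_dx:
            return None
        return dy.reshape(self._shape)


class Dense(_Layer):
    def __init__(self, in_f: int, out_f: int, relu: bool = False):
        super().__init__()
        self.in_f, self.out_f, self.relu = in_f, out_f, relu
        self.w = np.zeros((in_f, out_f), np.float32)
        self.b = np.zeros(out_f, np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def init(self, rng: np.random.Generator) -> None:
        self.w[...] = _glorot(rng, self.w.shape, self.in_f, self.out_f)
        self.b[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.w + self.b
        if self.relu:
            self._mask = y > 0
            y *= self._mask
        return y

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        if self.relu:
            dy = dy * self._mask
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        if not need_dx:
            return None
        return dy @ self.w.T


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        a = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= a * m / (np.sqrt(v) + self.eps)


class SequentialNet:
    """An ordered layer stack with softmax/cross-entropy training."""

    def __init__(self, layers: list[_Layer], seed: int = 0):
        self.layers = layers
        rng = np.random.default_rng(seed)
        for layer in layers:
            layer.init(rng)

    # -- inference ---------------------------------------------------------
    def logits(self, x: np.ndarray, batch: int = 128) -> np.ndarray:
        outs = []
        for i in range(0, len(x), batch):
            h = np.asarray(x[i : i + batch], np.float32)
            for layer in self.layers:
                h = layer.forward(h)
            outs.append(h)
        return np.concatenate(outs)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.logits(x))

    # -- training ----------------------------------------------------------
    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        n_classes: int,
        epochs: int,
        batch_size: int,
        learning_rate: float,
        seed: int = 0,
        trainable: str = "all",
    ) -> list[float]:
        """Minibatch Adam training; returns per-epoch mean cross-entropy.

        ``trainable='head'`` updates only the final Dense layer and skips the
        backward pass below it (the feature extractor stays bitwise frozen).
        """
        x = np.asarray(x, np.float32)
        y = np.asarray(y)
        if trainable == "all":
            first = 0
        elif trainable == "head":
            first = max(
                i for i, l in enumerate(self.layers) if isinstance(l, Dense)
            )
        else:
            raise ValueError(f"unknown trainable mode {trainable!r}")
        live = [l for l in self.layers[first:] if l.params]
        opt = _Adam([p for l in live for p in l.params], lr=learning_rate)
        rng = np.random.default_rng(seed)
        history = []
        n = len(x)
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for i in range(0, n, batch_size):
                idx = order[i : i + batch_size]
                xb, yb = x[idx], y[idx]
                h = xb
                for layer in self.layers:
                    h = layer.forward(h)
                p = softmax(h)
                losses.append(
                    float(-np.mean(np.log(p[np.arange(len(yb)), yb] + 1e-12)))
                )
                d = p
                d[np.arange(len(yb)), yb] -= 1.0
                d /= len(yb)
                d = d.astype(np.float32)
                for j in range(len(self.layers) - 1, first - 1, -1):
                    d = self.layers[j].backward(d, need_dx=j > first)
                opt.step([g for l in live for g in l.grads])
            history.append(float(np.mean(losses)))
        return history

    # -- weights -----------------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [p for layer in self.layers for p in layer.params]
        if len(flat) != len(weights):
            raise ValueError("weight list length mismatch")
        for p, w in zip(flat, weights):
            p[...] = w

    def n_params(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)
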