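"""Minimal feed-forward layer zoo (numpy, float32, NHWC).

Every layer implements ``forward(x, training)`` and ``backward(grad)``;
``backward`` returns the gradient with respect to the layer input and
accumulates parameter gradients in ``self.grads``. Caches required by the
backward pass are stored on the layer, so a layer instance services one
forward/backward pair at a time (single-threaded training).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DTYPE = np.float32


@dataclass(frozen=True)
class LayerInfo:
    """One row of a model summary: what a layer is, not how it computes."""

    kind: str
    width: int | None
    activation: str | None
    trainable: bool


def _activate(z: np.ndarray, activation: str | None) -> np.ndarray:
    if activation is None or activation == "linear":
        return z
    if activation == "relu":
        return np.maximum(z, 0.0)
    if activation == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    if activation == "tanh":
        return np.tanh(z)
    if activation == "softmax":
        z = z - z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)
    raise ValueError(f"unknown activation: {activation!r}")


def _activation_grad(a: np.ndarray, activation: str | None) -> np.ndarray:
    """d(activation)/dz expressed through the activated value ``a``."""
    if activation is None or activation == "linear":
        return np.ones_like(a)
    if activation == "relu":
        return (a > 0).astype(a.dtype)
    if activation == "sigmoid":
        return a * (1.0 - a)
    if activation == "tanh":
        return 1.0 - a * a
    raise ValueError(f"no elementwise gradient for activation: {activation!r}")


class Layer:
    trainable: bool = False

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def describe(self) -> LayerInfo:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Dense(Layer):
    """Fully connected layer with an optional fused activation.

    ``softmax``/``sigmoid`` heads are trained against fused losses, so their
    ``backward`` expects the gradient with respect to the *pre-activation*
    logits (``skip_activation=True`` from the loss); elementwise activations
    differentiate normally.
    """

    def __init__(
        self,
        in_dim: int,
        units: int,
        activation: str | None = "relu",
        *,
        rng: np.random.Generator,
        trainable: bool = True,
    ) -> None:
        super().__init__()
        self.in_dim = int(in_dim)
        self.units = int(units)
        self.activation = activation
        self.trainable = trainable
        if activation == "relu":
            scale = np.sqrt(2.0 / in_dim)  # He
        else:
            scale = np.sqrt(1.0 / in_dim)  # Lecun/Glorot-ish
        self.params["W"] = rng.normal(0.0, scale, size=(in_dim, units)).astype(DTYPE)
        self.params["b"] = np.zeros(units, dtype=DTYPE)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        self._a = _activate(z, self.activation)
        return self._a

    def backward(self, grad: np.ndarray, skip_activation: bool = False) -> np.ndarray:
        if not skip_activation and self.activation not in (None, "linear"):
            grad = grad * _activation_grad(self._a, self.activation)
        if self.trainable:
            self.grads["W"] = self._x.T @ grad
            self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T

    def describe(self) -> LayerInfo:
        return LayerInfo("dense", self.units, self.activation, self.trainable)


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float, *, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1): {rate}")
        self.rate = float(rate)
        self._rng = rng

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self._rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask

    def describe(self) -> LayerInfo:
        return LayerInfo("dropout", None, None, False)


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)

    def describe(self) -> LayerInfo:
        return LayerInfo("flatten", None, None, False)


class Conv2D(Layer):
    """3x3/1x1/5x5... convolution over NHWC via im2col + one matmul."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        padding: str = "valid",
        activation: str | None = "relu",
        *,
        rng: np.random.Generator,
        trainable: bool = True,
    ) -> None:
        super().__init__()
        if padding not in ("valid", "same"):
            raise ValueError(f"padding must be 'valid' or 'same': {padding!r}")
        self.in_channels = int(in_channels)
        self.out_channels = int(out_channels)
        self.kernel_size = int(kernel_size)
        self.stride = int(stride)
        self.padding = padding
        self.activation = activation
        self.trainable = trainable
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.params["W"] = rng.normal(
            0.0, scale, size=(kernel_size, kernel_size, in_channels, out_channels)
        ).astype(DTYPE)
        self.params["b"] = np.zeros(out_channels, dtype=DTYPE)

    def _pad_width(self, size: int) -> tuple[int, int]:
        if self.padding == "valid":
            return (0, 0)
        k, s = self.kernel_size, self.stride
        out = -(-size // s)  # ceil
        total = max((out - 1) * s + k - size, 0)
        return (total // 2, total - total // 2)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        k, s = self.kernel_size, self.stride
        ph, pw = self._pad_width(x.shape[1]), self._pad_width(x.shape[2])
        xp = np.pad(x, ((0, 0), ph, pw, (0, 0))) if (ph != (0, 0) or pw != (0, 0)) else x
        n, hp, wp, c = xp.shape
        oh = (hp - k) // s + 1
        ow = (wp - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        win = win[:, ::s, ::s]  # (n, oh, ow, c, k, k)
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * oh * ow, k * k * c
        )
        wm = self.params["W"].reshape(k * k * c, self.out_channels)
        z = (cols @ wm + self.params["b"]).reshape(n, oh, ow, self.out_channels)
        self._cache = (cols, xp.shape, (ph, pw), (n, oh, ow))
        self._a = _activate(z, self.activation)
        return self._a

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, xp_shape, (ph, pw), (n, oh, ow) = self._cache
        k, s, c = self.kernel_size, self.stride, self.in_channels
        if self.activation not in (None, "linear"):
            grad = grad * _activation_grad(self._a, self.activation)
        gm = grad.reshape(n * oh * ow, self.out_channels)
        wm = self.params["W"].reshape(k * k * c, self.out_channels)
        if self.trainable:
            self.grads["W"] = (cols.T @ gm).reshape(self.params["W"].shape)
            self.grads["b"] = gm.sum(axis=0)
        dcols = (gm @ wm.T).reshape(n, oh, ow, k, k, c)
        dxp = np.zeros(xp_shape, dtype=grad.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + oh * s : s, j : j + ow * s : s, :] += dcols[:, :, :, i, j, :]
        h0, h1 = ph[0], xp_shape[1] - ph[1]
        w0, w1 = pw[0], xp_shape[2] - pw[1]
        return dxp[:, h0:h1, w0:w1, :]

    def describe(self) -> LayerInfo:
        return LayerInfo("conv2d", self.out_channels, self.activation, self.trainable)


class MaxPool2D(Layer):
    """2x2 (or pxp) max pooling with stride = pool size; odd remainders cropped."""

    def __init__(self, pool_size: int = 2) -> None:
        super().__init__()
        self.pool_size = int(pool_size)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        p = self.pool_size
        n, h, w, c = x.shape
        oh, ow = h // p, w // p
        xc = x[:, : oh * p, : ow * p, :]
        self._in_shape = x.shape
        blocks = xc.reshape(n, oh, p, ow, p, c)
        out = blocks.max(axis=(2, 4))
        self._mask = blocks == out[:, :, None, :, None, :]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        p = self.pool_size
        n, oh, ow, c = grad.shape
        g = self._mask * grad[:, :, None, :, None, :]
        # split ties evenly so gradient mass is conserved
        counts = self._mask.sum(axis=(2, 4), keepdims=True)
        g = (g / counts).reshape(n, oh * p, ow * p, c)
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        dx[:, : oh * p, : ow * p, :] = g
        return dx

    def describe(self) -> LayerInfo:
        return LayerInfo("maxpool2d", None, None, False)


class GlobalAveragePool2D(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        return np.broadcast_to(grad[:, None, None, :] / (h * w), self._in_shape).astype(
            grad.dtype
        )

    def describe(self) -> LayerInfo:
        return LayerInfo("globalavgpool2d", None, None, False)


class LSTM(Layer):
    """Single LSTM layer over (N, T, D) input, optionally returning sequences.

    Gate activations are sigmoid; the candidate/output activation is
    configurable (the location branch uses ReLU throughout).
    """

    def __init__(
        self,
        input_size: int,
        units: int,
        *,
        return_sequences: bool,
        activation: str = "relu",
        rng: np.random.Generator,
        trainable: bool = True,
    ) -> None:
        super().__init__()
        self.input_size = int(input_size)
        self.units = int(units)
        self.return_sequences = bool(return_sequences)
        self.activation = activation
        self.trainable = trainable
        u = self.units
        scale_x = np.sqrt(1.0 / input_size)
        scale_h = np.sqrt(1.0 / u)
        self.params["Wx"] = rng.normal(0.0, scale_x, size=(input_size, 4 * u)).astype(DTYPE)
        self.params["Wh"] = rng.normal(0.0, scale_h, size=(u, 4 * u)).astype(DTYPE)
        b = np.zeros(4 * u, dtype=DTYPE)
        b[u : 2 * u] = 1.0  # forget-gate bias
        self.params["b"] = b

    def _act(self, z: np.ndarray) -> np.ndarray:
        return _activate(z, self.activation)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, t, d = x.shape
        u = self.units
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((n, u), dtype=DTYPE)
        c = np.zeros((n, u), dtype=DTYPE)
        self._x = x
        self._steps = []
        hs = np.empty((n, t, u), dtype=DTYPE)
        for ti in range(t):
            z = x[:, ti, :] @ Wx + h @ Wh + b
            i = _activate(z[:, :u], "sigmoid")
            f = _activate(z[:, u : 2 * u], "sigmoid")
            o = _activate(z[:, 2 * u : 3 * u], "sigmoid")
            g = self._act(z[:, 3 * u :])
            c_new = f * c + i * g
            ac = self._act(c_new)
            h_new = o * ac
            self._steps.append((h, c, i, f, o, g, c_new, ac))
            h, c = h_new, c_new
            hs[:, ti, :] = h
        self._hs = hs
        return hs if self.return_sequences else h

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, steps = self._x, self._steps
        n, t, d = x.shape
        u = self.units
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params["b"])
        dx = np.empty_like(x)
        dh_next = np.zeros((n, u), dtype=DTYPE)
        dc_next = np.zeros((n, u), dtype=DTYPE)
        for ti in range(t - 1, -1, -1):
            h_prev, c_prev, i, f, o, g, c_new, ac = steps[ti]
            dh = dh_next + (grad[:, ti, :] if self.return_sequences else 0)
            if not self.return_sequences and ti == t - 1:
                dh = dh + grad
            do = dh * ac
            dc = dh * o * _activation_grad(ac, self.activation) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    do * o * (1 - o),
                    dg * _activation_grad(g, self.activation),
                ],
                axis=1,
            )
            if self.trainable:
                dWx += x[:, ti, :].T @ dz
                dWh += h_prev.T @ dz
                db += dz.sum(axis=0)
            dx[:, ti, :] = dz @ Wx.T
            dh_next = dz @ Wh.T
            dc_next = dc * f
        if self.trainable:
            self.grads["Wx"], self.grads["Wh"], self.grads["b"] = dWx, dWh, db
        return dx

    def describe(self) -> LayerInfo:
        return LayerInfo("lstm", self.units, self.activation, self.trainable)


class Reshape(Layer):
    """Static reshape of the non-batch dimensions (e.g. one-hot -> (T, 1))."""

    def __init__(self, target_shape: tuple[int, ...]) -> None:
        super().__init__()
        self.target_shape = tuple(int(s) for s in target_shape)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.target_shape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)

    def describe(self) -> LayerInfo:
        return LayerInfo("reshape", None, None, False)
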