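"""Network containers: sequential stacks, residual/branch blocks, late fusion."""

from __future__ import annotations

import numpy as np

from .layers import Dense, Layer, LayerInfo, _activate, _activation_grad


class Sequential(Layer):
    """A plain stack of layers; itself usable as a layer inside another stack."""

    def __init__(self, layers: list[Layer], name: str = "sequential") -> None:
        super().__init__()
        self.layers = list(layers)
        self.name = name

    @property
    def trainable(self) -> bool:  # type: ignore[override]
        return any(l.trainable for l in self.layers)

    @trainable.setter
    def trainable(self, value: bool) -> None:
        for l in self.layers:
            l.trainable = value

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray, skip_activation: bool = False) -> np.ndarray:
        # Stop once no trainable parameters remain below: frozen backbones
        # never need input gradients.
        lowest = None
        for idx, layer in enumerate(self.layers):
            if layer.trainable:
                lowest = idx
                break
        for idx in range(len(self.layers) - 1, -1, -1):
            layer = self.layers[idx]
            if lowest is None or idx < lowest:
                break
            if isinstance(layer, Dense) and skip_activation and idx == len(self.layers) - 1:
                grad = layer.backward(grad, skip_activation=True)
            else:
                grad = layer.backward(grad)
        return grad

    def describe(self) -> list[LayerInfo]:
        out: list[LayerInfo] = []
        for layer in self.layers:
            d = layer.describe()
            out.extend(d if isinstance(d, list) else [d])
        return out

    def iter_trainable(self):
        for layer in self.layers:
            if isinstance(layer, (Sequential, ResidualBlock, BranchBlock)):
                yield from layer.iter_trainable()
            elif layer.trainable and layer.params:
                yield layer

    def iter_all(self):
        for layer in self.layers:
            if isinstance(layer, (Sequential, ResidualBlock, BranchBlock)):
                yield from layer.iter_all()
            elif layer.params:
                yield layer

    @property
    def n_params(self) -> int:  # type: ignore[override]
        return sum(l.n_params for l in self.iter_all())


class ResidualBlock(Layer):
    """y = act(F(x) + shortcut(x)); shortcut is identity or a projection stack."""

    def __init__(
        self,
        body: Sequential,
        shortcut: Sequential | None = None,
        activation: str = "relu",
    ) -> None:
        super().__init__()
        self.body = body
        self.shortcut = shortcut
        self.activation = activation

    @property
    def trainable(self) -> bool:  # type: ignore[override]
        return self.body.trainable or (self.shortcut is not None and self.shortcut.trainable)

    @trainable.setter
    def trainable(self, value: bool) -> None:
        self.body.trainable = value
        if self.shortcut is not None:
            self.shortcut.trainable = value

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        f = self.body.forward(x, training)
        s = self.shortcut.forward(x, training) if self.shortcut is not None else x
        self._a = _activate(f + s, self.activation)
        return self._a

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = grad * _activation_grad(self._a, self.activation)
        dx = self.body.backward(grad)
        if self.shortcut is not None:
            dx = dx + self.shortcut.backward(grad)
        else:
            dx = dx + grad
        return dx

    def describe(self) -> list[LayerInfo]:
        width = self.body.describe()[-1].width
        return [LayerInfo("residual_block", width, self.activation, self.trainable)]

    def iter_trainable(self):
        yield from self.body.iter_trainable()
        if self.shortcut is not None:
            yield from self.shortcut.iter_trainable()

    def iter_all(self):
        yield from self.body.iter_all()
        if self.shortcut is not None:
            yield from self.shortcut.iter_all()

    @property
    def n_params(self) -> int:  # type: ignore[override]
        n = self.body.n_params
        if self.shortcut is not None:
            n += self.shortcut.n_params
        return n


class BranchBlock(Layer):
    """Parallel branches over one input, concatenated on the channel axis."""

    def __init__(self, branches: list[Sequential]) -> None:
        super().__init__()
        self.branches = branches

    @property
    def trainable(self) -> bool:  # type: ignore[override]
        return any(b.trainable for b in self.branches)

    @trainable.setter
    def trainable(self, value: bool) -> None:
        for b in self.branches:
            b.trainable = value

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        outs = [b.forward(x, training) for b in self.branches]
        self._widths = [o.shape[-1] for o in outs]
        return np.concatenate(outs, axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dx = None
        offset = 0
        for b, w in zip(self.branches, self._widths):
            g = grad[..., offset : offset + w]
            offset += w
            d = b.backward(g)
            dx = d if dx is None else dx + d
        return dx

    def describe(self) -> list[LayerInfo]:
        return [LayerInfo("branch_block", sum(len(b.layers) for b in self.branches), None, self.trainable)]

    def iter_trainable(self):
        for b in self.branches:
            yield from b.iter_trainable()

    def iter_all(self):
        for b in self.branches:
            yield from b.iter_all()

    @property
    def n_params(self) -> int:  # type: ignore[override]
        return sum(b.n_params for b in self.branches)


class FusionNetwork:
    """Two (or more) input branches whose outputs are concatenated into a head.

    ``forward`` takes a tuple/list of per-branch inputs in branch order.
    """

    def __init__(self, branches: list[Sequential], head: Sequential) -> None:
        self.branches = branches
        self.head = head

    def forward(self, xs, training: bool = False) -> np.ndarray:
        if len(xs) != len(self.branches):
            raise ValueError(f"expected {len(self.branches)} inputs, got {len(xs)}")
        outs = [b.forward(x, training) for b, x in zip(self.branches, xs)]
        self._widths = [o.shape[-1] for o in outs]
        return self.head.forward(np.concatenate(outs, axis=-1), training)

    def backward(self, grad: np.ndarray, skip_activation: bool = False) -> None:
        g = self.head.backward(grad, skip_activation=skip_activation)
        offset = 0
        for b, w in zip(self.branches, self._widths):
            if b.trainable:
                b.backward(g[:, offset : offset + w])
            offset += w

    def describe(self) -> list[LayerInfo]:
        out: list[LayerInfo] = []
        for i, b in enumerate(self.branches):
            out.append(LayerInfo(f"branch[{i}]", None, None, b.trainable))
            out.extend(b.describe())
        out.append(LayerInfo("concatenate", sum_or_none(self._terminal_widths()), None, False))
        out.extend(self.head.describe())
        return out

    def _terminal_widths(self) -> list[int | None]:
        widths: list[int | None] = []
        for b in self.branches:
            width = None
            for info in reversed(b.describe()):
                if info.width is not None:
                    width = info.width
                    break
            widths.append(width)
        return widths

    def iter_trainable(self):
        for b in self.branches:
            yield from b.iter_trainable()
        yield from self.head.iter_trainable()

    def iter_all(self):
        for b in self.branches:
            yield from b.iter_all()
        yield from self.head.iter_all()

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.iter_all())


def sum_or_none(widths) -> int | None:
    if any(w is None for w in widths):
        return None
    return int(sum(widths))


def get_weights(net) -> list[np.ndarray]:
    """Flat snapshot of every parameter array (copy), frozen ones included."""
    out = []
    for layer in net.iter_all():
        for name in sorted(layer.params):
            out.append(layer.params[name].copy())
    return out


def set_weights(net, weights: list[np.ndarray]) -> None:
    it = iter(weights)
    for layer in net.iter_all():
        for name in sorted(layer.params):
            w = next(it)
            if layer.params[name].shape != w.shape:
                raise ValueError("weight shape mismatch while restoring checkpoint")
            layer.params[name] = w.copy()
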