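"""Numerical correctness of the layer engine: gradients, losses, dropout."""

import numpy as np
import pytest

import woundmm.nn.layers as layers_mod
from woundmm.nn import (
    Adam,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    LSTM,
    MaxPool2D,
    Sequential,
    binary_crossentropy,
    get_weights,
    set_weights,
    sparse_categorical_crossentropy,
)


def to_float64(net):
    for layer in net.iter_all():
        for k in layer.params:
            layer.params[k] = layer.params[k].astype(np.float64)


def max_rel_grad_error(net, x, y, loss_fn, n_probe=8):
    """Compare backprop gradients against central differences."""
    probs = net.forward(x)
    _, dl = loss_fn(probs, y)
    net.backward(dl, skip_activation=True)
    worst = 0.0
    for layer in net.iter_all():
        for name, grad in layer.grads.items():
            flat = layer.params[name].ravel()
            sel = np.linspace(0, flat.size - 1, min(n_probe, flat.size)).astype(int)
            for i in sel:
                old = flat[i]
                eps = 1e-6
                flat[i] = old + eps
                l1, _ = loss_fn(net.forward(x), y)
                flat[i] = old - eps
                l2, _ = loss_fn(net.forward(x), y)
                flat[i] = old
                num = (l1 - l2) / (2 * eps)
                ana = grad.ravel()[i]
                worst = max(worst, abs(num - ana) / (abs(num) + abs(ana) + 1e-9))
    return worst


@pytest.fixture(autouse=True)
def float64_engine(monkeypatch):
    monkeypatch.setattr(layers_mod, "DTYPE", np.float64)
    yield


class TestGradients:
    def test_conv_pool_dense_stack(self):
        rng = np.random.default_rng(0)
        net = Sequential(
            [
                Conv2D(3, 4, 3, rng=rng, activation="tanh"),
                MaxPool2D(2),
                Flatten(),
                Dense(4 * 3 * 3, 8, activation="tanh", rng=rng),
                Dense(8, 3, activation="softmax", rng=rng),
            ]
        )
        to_float64(net)
        x = rng.normal(size=(5, 8, 8, 3))
        y = np.array([0, 1, 2, 0, 1])
        assert max_rel_grad_error(net, x, y, sparse_categorical_crossentropy) < 1e-6

    def test_strided_same_padding_conv(self):
        rng = np.random.default_rng(1)
        net = Sequential(
            [
                Conv2D(2, 5, 3, stride=2, padding="same", rng=rng, activation="tanh"),
                Flatten(),
                Dense(5 * 4 * 4, 3, activation="softmax", rng=rng),
            ]
        )
        to_float64(net)
        x = rng.normal(size=(3, 7, 7, 2))
        y = np.array([0, 1, 2])
        assert max_rel_grad_error(net, x, y, sparse_categorical_crossentropy) < 1e-6

    def test_lstm_stack_bptt(self):
        rng = np.random.default_rng(2)
        net = Sequential(
            [
                LSTM(2, 4, return_sequences=True, activation="tanh", rng=rng),
                LSTM(4, 3, return_sequences=False, activation="tanh", rng=rng),
                Dense(3, 3, activation="softmax", rng=rng),
            ]
        )
        to_float64(net)
        x = rng.normal(size=(4, 6, 2))
        y = np.array([0, 1, 2, 1])
        assert max_rel_grad_error(net, x, y, sparse_categorical_crossentropy) < 1e-5

    def test_sigmoid_head_binary_loss(self):
        rng = np.random.default_rng(3)
        net = Sequential(
            [
                Dense(6, 5, activation="tanh", rng=rng),
                Dense(5, 1, activation="sigmoid", rng=rng),
            ]
        )
        to_float64(net)
        x = rng.normal(size=(7, 6))
        y = np.array([0, 1, 1, 0, 1, 0, 0])
        assert max_rel_grad_error(net, x, y, binary_crossentropy) < 1e-6


class TestLossValues:
    def test_categorical_loss_matches_manual_nll(self):
        probs = np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1]])
        y = np.array([0, 1])
        loss, _ = sparse_categorical_crossentropy(probs, y)
        assert loss == pytest.approx(-(np.log(0.7) + np.log(0.8)) / 2)

    def test_binary_loss_matches_manual_bce(self):
        probs = np.array([[0.9], [0.2]])
        y = np.array([1, 0])
        loss, _ = binary_crossentropy(probs, y)
        assert loss == pytest.approx(-(np.log(0.9) + np.log(0.8)) / 2)


class TestDropoutAndAdam:
    def test_dropout_identity_at_eval_scaled_mask_at_train(self):
        rng = np.random.default_rng(0)
        drop = Dropout(0.5, rng=rng)
        x = np.ones((200, 50))
        assert np.array_equal(drop.forward(x, training=False), x)
        out = drop.forward(x, training=True)
        kept = out[out != 0]
        assert np.allclose(kept, 2.0)  # inverted scaling 1/(1-p)
        assert 0.3 < (out != 0).mean() < 0.7

    def test_adam_decreases_loss_on_convex_problem(self):
        rng = np.random.default_rng(0)
        net = Sequential([Dense(4, 3, activation="softmax", rng=rng)])
        x = rng.normal(size=(64, 4)).astype(np.float64)
        y = (x[:, 0] > 0).astype(int) + (x[:, 1] > 0).astype(int)
        to_float64(net)
        opt = Adam(learning_rate=0.05)
        first = None
        for _ in range(60):
            probs = net.forward(x)
            loss, dl = sparse_categorical_crossentropy(probs, y)
            first = loss if first is None else first
            net.backward(dl, skip_activation=True)
            opt.step(net.iter_trainable())
        assert loss < first * 0.5

    def test_weight_snapshot_roundtrip(self):
        rng = np.random.default_rng(0)
        net = Sequential([Dense(3, 2, rng=rng), Dense(2, 2, activation="softmax", rng=rng)])
        snap = get_weights(net)
        for layer in net.iter_all():
            for k in layer.params:
                layer.params[k] = layer.params[k] + 1.0
        set_weights(net, snap)
        for a, b in zip(get_weights(net), snap):
            np.testing.assert_array_equal(a, b)
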