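"""The three network families: image (WIC), location (WLC), fused (WMC).

WIC — an image backbone (frozen for the transfer-learning backbones,
trainable for AlexNet and the small TinyTest stack) under a head of three
Dense(512, ReLU) layers, each followed by dropout.

WLC — either a 9-layer ReLU MLP over the one-hot location vector
(widths 128,128,128,256,256,256,512,512,512) or a recurrent stack of four
LSTM layers (32,32,64,64 units) and a Dense(512) layer.

WMC — late fusion: the two branches' terminal 512-wide representations (or,
optionally, their class-probability outputs) are concatenated and passed
through Dense(512) and Dense(256) before the output layer.

Output layers follow one rule everywhere: softmax of width ``n_classes``
for multi-class problems, a single sigmoid unit for binary ones.

All backbones are randomly initialized re-implementations built on the
package's own layer engine; no pretrained weights are distributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    BranchBlock,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    FusionNetwork,
    GlobalAveragePool2D,
    LSTM,
    LayerInfo,
    MaxPool2D,
    Reshape,
    ResidualBlock,
    Sequential,
)
from .nn.layers import Layer

WIC_HEAD_WIDTHS = (512, 512, 512)
WLC_MLP_WIDTHS = (128, 128, 128, 256, 256, 256, 512, 512, 512)
WLC_LSTM_UNITS = (32, 32, 64, 64)
WLC_LSTM_DENSE = 512
WMC_POST_FUSION_WIDTHS = (512, 256)

BACKBONE_DEFAULTS: dict[str, tuple[int, bool]] = {
    # name -> (default input size, frozen by default)
    "vgg16": (224, True),
    "vgg19": (224, True),
    "resnet50": (224, True),
    "inceptionv3": (299, True),
    "alexnet": (227, False),
    "tinytest": (64, False),
}

__all__ = [
    "ArchitectureError",
    "BACKBONE_DEFAULTS",
    "ModelHandle",
    "WICConfig",
    "WLCConfig",
    "WMCConfig",
    "build_ohv_direct",
    "build_wic",
    "build_wlc",
    "build_wmc",
]


class ArchitectureError(ValueError):
    """Invalid architecture configuration."""


class Identity(Layer):
    """Pass-through layer; declares its width so summaries show fan-in."""

    def __init__(self, width: int) -> None:
        super().__init__()
        self.width = int(width)

    def forward(self, x, training: bool = False):
        return x

    def backward(self, grad):
        return grad

    def describe(self) -> LayerInfo:
        return LayerInfo("identity", self.width, None, False)


def _normalize_backbone(name: str) -> str:
    key = str(name).lower().replace("-", "").replace("_", "")
    if key not in BACKBONE_DEFAULTS:
        raise ArchitectureError(
            f"unknown backbone {name!r}; choose from {sorted(BACKBONE_DEFAULTS)}"
        )
    return key


@dataclass(frozen=True)
class WICConfig:
    """Wound image classifier: backbone + 3xDense(512,ReLU)+dropout + head."""

    n_classes: int
    backbone: str = "tinytest"
    input_size: int | None = None
    freeze_backbone: bool | None = None
    dropout_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        key = _normalize_backbone(self.backbone)
        object.__setattr__(self, "backbone", key)
        if self.n_classes < 2:
            raise ArchitectureError(f"n_classes must be >= 2: {self.n_classes}")
        size, frozen = BACKBONE_DEFAULTS[key]
        if self.input_size is None:
            object.__setattr__(self, "input_size", size)
        if self.freeze_backbone is None:
            object.__setattr__(self, "freeze_backbone", frozen)
        if self.input_size < 16:
            raise ArchitectureError(f"input_size too small for any backbone: {self.input_size}")


@dataclass(frozen=True)
class WLCConfig:
    """Wound location classifier over a one-hot location vector."""

    input_dim: int
    n_classes: int
    kind: str = "mlp"  # mlp | lstm
    sequence_shaping: str = "timesteps_of_1"  # lstm only: timesteps_of_1 | single_step
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("mlp", "lstm"):
            raise ArchitectureError(f"unknown WLC kind {self.kind!r} (mlp or lstm)")
        if self.sequence_shaping not in ("timesteps_of_1", "single_step"):
            raise ArchitectureError(f"unknown sequence shaping {self.sequence_shaping!r}")
        if self.input_dim < 2:
            raise ArchitectureError(f"input_dim must be >= 2: {self.input_dim}")
        if self.n_classes < 2:
            raise ArchitectureError(f"n_classes must be >= 2: {self.n_classes}")


@dataclass(frozen=True)
class WMCConfig:
    """Fused multi-modal classifier: WIC branch + WLC branch + fusion head."""

    wic: WICConfig
    wlc: WLCConfig
    fusion_point: str = "features"  # features | probabilities

    def __post_init__(self) -> None:
        if self.fusion_point not in ("features", "probabilities"):
            raise ArchitectureError(f"unknown fusion point {self.fusion_point!r}")
        if self.wic.n_classes != self.wlc.n_classes:
            raise ArchitectureError(
                f"branch n_classes mismatch: WIC {self.wic.n_classes} vs "
                f"WLC {self.wlc.n_classes}"
            )

    @property
    def n_classes(self) -> int:
        return self.wic.n_classes


@dataclass
class ModelHandle:
    """A built network plus the metadata needed to train and inspect it."""

    net: Sequential | FusionNetwork
    config: object
    n_classes: int
    input_kind: str  # image | location | multimodal
    rng: np.random.Generator = field(repr=False, default=None)

    @property
    def output_dim(self) -> int:
        return self.n_classes if self.n_classes > 2 else 1

    @property
    def loss_kind(self) -> str:
        return "categorical" if self.n_classes > 2 else "binary"

    def describe(self) -> list[LayerInfo]:
        return self.net.describe()

    def dense_widths(self, trainable_only: bool = False) -> list[int]:
        return [
            i.width
            for i in self.describe()
            if i.kind == "dense" and (i.trainable or not trainable_only)
        ]

    @property
    def n_params(self) -> int:
        return self.net.n_params

    @property
    def n_trainable_params(self) -> int:
        return int(
            sum(l.n_params for l in self.net.iter_trainable())
        )

    def forward(self, x, training: bool = False) -> np.ndarray:
        return self.net.forward(x, training)

    def predict_proba(self, x, batch_size: int = 64) -> np.ndarray:
        """Class probabilities; binary heads are expanded to two columns."""
        outs = []
        n = len(x[0]) if isinstance(x, (tuple, list)) else len(x)
        for start in range(0, n, batch_size):
            sl = slice(start, start + batch_size)
            xb = tuple(xi[sl] for xi in x) if isinstance(x, (tuple, list)) else x[sl]
            outs.append(self.net.forward(xb, training=False))
        p = np.concatenate(outs, axis=0)
        if self.n_classes == 2:
            p = np.hstack([1.0 - p, p])
        return p

    def predict(self, x, batch_size: int = 64) -> np.ndarray:
        """Argmax class indexes; ties break toward the lowest class index."""
        return np.argmax(self.predict_proba(x, batch_size), axis=1)


def _head_layer(in_dim: int, n_classes: int, rng: np.random.Generator) -> Dense:
    if n_classes > 2:
        return Dense(in_dim, n_classes, activation="softmax", rng=rng)
    return Dense(in_dim, 1, activation="sigmoid", rng=rng)


def _dense_dropout_head(
    in_dim: int, dropout_rate: float, rng: np.random.Generator
) -> tuple[list, int]:
    layers: list = []
    d = in_dim
    for width in WIC_HEAD_WIDTHS:
        layers.append(Dense(d, width, activation="relu", rng=rng))
        layers.append(Dropout(dropout_rate, rng=rng))
        d = width
    return layers, d


# ---------------------------------------------------------------------------
# Backbones. Each builder returns (Sequential, flat feature width).
# ---------------------------------------------------------------------------


def _conv_out(size: int, k: int, stride: int, padding: str) -> int:
    if padding == "same":
        return -(-size // stride)
    return (size - k) // stride + 1


def _vgg(sizes: list[list[int]], in_size: int, rng) -> tuple[Sequential, int]:
    layers: list = []
    c = 3
    s = in_size
    for block in sizes:
        for width in block:
            layers.append(Conv2D(c, width, 3, padding="same", activation="relu", rng=rng))
            c = width
        layers.append(MaxPool2D(2))
        s //= 2
    layers.append(Flatten())
    return Sequential(layers, name="vgg"), s * s * c


def _build_vgg16(in_size: int, rng) -> tuple[Sequential, int]:
    return _vgg([[64] * 2, [128] * 2, [256] * 3, [512] * 3, [512] * 3], in_size, rng)


def _build_vgg19(in_size: int, rng) -> tuple[Sequential, int]:
    return _vgg([[64] * 2, [128] * 2, [256] * 4, [512] * 4, [512] * 4], in_size, rng)


def _build_alexnet(in_size: int, rng) -> tuple[Sequential, int]:
    layers = [
        Conv2D(3, 96, 11, stride=4, padding="valid", activation="relu", rng=rng),
        MaxPool2D(2),
        Conv2D(96, 256, 5, padding="same", activation="relu", rng=rng),
        MaxPool2D(2),
        Conv2D(256, 384, 3, padding="same", activation="relu", rng=rng),
        Conv2D(384, 384, 3, padding="same", activation="relu", rng=rng),
        Conv2D(384, 256, 3, padding="same", activation="relu", rng=rng),
        MaxPool2D(2),
        Flatten(),
    ]
    s = _conv_out(in_size, 11, 4, "valid") // 2 // 2 // 2
    return Sequential(layers, name="alexnet"), s * s * 256


def _build_tinytest(in_size: int, rng) -> tuple[Sequential, int]:
    layers = [
        Conv2D(3, 8, 3, padding="valid", activation="relu", rng=rng),
        MaxPool2D(2),
        Conv2D(8, 16, 3, padding="valid", activation="relu", rng=rng),
        MaxPool2D(2),
        Flatten(),
    ]
    s = ((in_size - 2) // 2 - 2) // 2
    return Sequential(layers, name="tinytest"), s * s * 16


def _bottleneck(c_in: int, width: int, stride: int, project: bool, rng) -> ResidualBlock:
    body = Sequential(
        [
            Conv2D(c_in, width, 1, padding="same", activation="relu", rng=rng),
            Conv2D(width, width, 3, stride=stride, padding="same", activation="relu", rng=rng),
            Conv2D(width, 4 * width, 1, padding="same", activation=None, rng=rng),
        ]
    )
    shortcut = None
    if project:
        shortcut = Sequential(
            [Conv2D(c_in, 4 * width, 1, stride=stride, padding="same", activation=None, rng=rng)]
        )
    return ResidualBlock(body, shortcut)


def _build_resnet50(in_size: int, rng) -> tuple[Sequential, int]:
    layers: list = [
        Conv2D(3, 64, 7, stride=2, padding="same", activation="relu", rng=rng),
        MaxPool2D(2),
    ]
    c = 64
    for width, blocks, stride in [(64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2)]:
        for b in range(blocks):
            s = stride if b == 0 else 1
            layers.append(_bottleneck(c, width, s, project=(b == 0), rng=rng))
            c = 4 * width
    layers.append(GlobalAveragePool2D())
    return Sequential(layers, name="resnet50"), 2048


def _inception_block(c_in: int, w1: int, w3: tuple[int, int], w5: tuple[int, int, int], rng) -> BranchBlock:
    return BranchBlock(
        [
            Sequential([Conv2D(c_in, w1, 1, padding="same", activation="relu", rng=rng)]),
            Sequential(
                [
                    Conv2D(c_in, w3[0], 1, padding="same", activation="relu", rng=rng),
                    Conv2D(w3[0], w3[1], 3, padding="same", activation="relu", rng=rng),
                ]
            ),
            Sequential(
                [
                    Conv2D(c_in, w5[0], 1, padding="same", activation="relu", rng=rng),
                    Conv2D(w5[0], w5[1], 3, padding="same", activation="relu", rng=rng),
                    Conv2D(w5[1], w5[2], 3, padding="same", activation="relu", rng=rng),
                ]
            ),
        ]
    )


def _build_inceptionv3(in_size: int, rng) -> tuple[Sequential, int]:
    """Reduced Inception-style backbone: conv stem + three mixed branch
    blocks ending in a 2048-wide global-average-pooled feature."""
    layers: list = [
        Conv2D(3, 32, 3, stride=2, padding="valid", activation="relu", rng=rng),
        Conv2D(32, 64, 3, padding="same", activation="relu", rng=rng),
        MaxPool2D(2),
        _inception_block(64, 64, (48, 64), (64, 96, 96), rng),
        MaxPool2D(2),
        _inception_block(224, 192, (128, 192), (128, 192, 192), rng),
        MaxPool2D(2),
        _inception_block(576, 768, (256, 768), (256, 512, 512), rng),
        GlobalAveragePool2D(),
    ]
    return Sequential(layers, name="inceptionv3"), 2048


_BACKBONE_BUILDERS = {
    "vgg16": _build_vgg16,
    "vgg19": _build_vgg19,
    "alexnet": _build_alexnet,
    "resnet50": _build_resnet50,
    "inceptionv3": _build_inceptionv3,
    "tinytest": _build_tinytest,
}


def _build_backbone(config: WICConfig, rng) -> tuple[Sequential, int]:
    backbone, feat_dim = _BACKBONE_BUILDERS[config.backbone](config.input_size, rng)
    if feat_dim <= 0:
        raise ArchitectureError(
            f"input_size {config.input_size} incompatible with backbone {config.backbone}"
        )
    if config.freeze_backbone:
        backbone.trainable = False
    return backbone, feat_dim


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------


def build_wic(config: WICConfig) -> ModelHandle:
    """Image classifier: (frozen) backbone, three Dense(512)+dropout, head."""
    rng = np.random.default_rng(config.seed)
    backbone, feat_dim = _build_backbone(config, rng)
    head, d = _dense_dropout_head(feat_dim, config.dropout_rate, rng)
    net = Sequential([backbone, *head, _head_layer(d, config.n_classes, rng)], name="wic")
    return ModelHandle(net, config, config.n_classes, "image", rng)


def _wlc_trunk(config: WLCConfig, rng) -> list:
    """WLC layers up to (and including) the terminal 512-wide representation."""
    if config.kind == "mlp":
        layers: list = []
        d = config.input_dim
        for width in WLC_MLP_WIDTHS:
            layers.append(Dense(d, width, activation="relu", rng=rng))
            d = width
        return layers
    if config.sequence_shaping == "timesteps_of_1":
        shape = (config.input_dim, 1)
        feat = 1
    else:
        shape = (1, config.input_dim)
        feat = config.input_dim
    layers = [Reshape(shape)]
    d = feat
    for i, units in enumerate(WLC_LSTM_UNITS):
        last = i == len(WLC_LSTM_UNITS) - 1
        layers.append(
            LSTM(d, units, return_sequences=not last, activation="relu", rng=rng)
        )
        d = units
    layers.append(Dense(d, WLC_LSTM_DENSE, activation="relu", rng=rng))
    return layers


def build_wlc(config: WLCConfig) -> ModelHandle:
    """Location classifier: 9-dense MLP or 4-layer LSTM + Dense(512), + head."""
    rng = np.random.default_rng(config.seed)
    trunk = _wlc_trunk(config, rng)
    net = Sequential([*trunk, _head_layer(512, config.n_classes, rng)], name="wlc")
    return ModelHandle(net, config, config.n_classes, "location", rng)


def build_wmc(config: WMCConfig) -> ModelHandle:
    """Fused classifier: branch outputs concatenated, Dense(512), Dense(256), head.

    With ``fusion_point='features'`` each branch contributes its terminal
    512-wide hidden representation (concat width 1024); with
    ``'probabilities'`` each contributes its class output (concat width
    2 x output width).
    """
    rng = np.random.default_rng(config.wic.seed)
    backbone, feat_dim = _build_backbone(config.wic, rng)
    img_head, d_img = _dense_dropout_head(feat_dim, config.wic.dropout_rate, rng)
    loc_trunk = _wlc_trunk(config.wlc, rng)
    if config.fusion_point == "features":
        img_branch = Sequential([backbone, *img_head], name="wic-branch")
        loc_branch = Sequential(loc_trunk, name="wlc-branch")
        concat_dim = d_img + 512
    else:
        out_dim = config.n_classes if config.n_classes > 2 else 1
        img_branch = Sequential(
            [backbone, *img_head, _head_layer(d_img, config.n_classes, rng)],
            name="wic-branch",
        )
        loc_branch = Sequential(
            [*loc_trunk, _head_layer(512, config.n_classes, rng)], name="wlc-branch"
        )
        concat_dim = 2 * out_dim
    fusion_layers: list = []
    d = concat_dim
    for width in WMC_POST_FUSION_WIDTHS:
        fusion_layers.append(Dense(d, width, activation="relu", rng=rng))
        d = width
    fusion_layers.append(_head_layer(d, config.n_classes, rng))
    net = FusionNetwork([img_branch, loc_branch], Sequential(fusion_layers, name="fusion-head"))
    return ModelHandle(net, config, config.n_classes, "multimodal", rng)


def config_to_yaml(config: WICConfig | WLCConfig | WMCConfig, path) -> None:
    """Serialize an architecture config (nested for WMC) as YAML."""
    import yaml
    from dataclasses import asdict
    from pathlib import Path

    kind = type(config).__name__
    Path(path).write_text(yaml.safe_dump({"kind": kind, "config": asdict(config)}))


def config_from_yaml(path) -> WICConfig | WLCConfig | WMCConfig:
    """Load an architecture config written by :func:`config_to_yaml`."""
    import yaml
    from pathlib import Path

    payload = yaml.safe_load(Path(path).read_text())
    kind = payload.get("kind")
    cfg = payload.get("config", {})
    if kind == "WICConfig":
        return WICConfig(**cfg)
    if kind == "WLCConfig":
        return WLCConfig(**cfg)
    if kind == "WMCConfig":
        return WMCConfig(
            wic=WICConfig(**cfg["wic"]), wlc=WLCConfig(**cfg["wlc"]),
            fusion_point=cfg.get("fusion_point", "features"),
        )
    raise ArchitectureError(f"unknown config kind {kind!r} in {path}")


def build_from_config(config: WICConfig | WLCConfig | WMCConfig) -> ModelHandle:
    if isinstance(config, WMCConfig):
        return build_wmc(config)
    if isinstance(config, WLCConfig):
        return build_wlc(config)
    return build_wic(config)


def build_ohv_direct(config: WICConfig, location_dim: int) -> ModelHandle:
    """Image backbone with the raw one-hot location vector concatenated
    straight into the dense head (no WLC stack at all)."""
    rng = np.random.default_rng(config.seed)
    backbone, feat_dim = _build_backbone(config, rng)
    img_branch = Sequential([backbone], name="image-features")
    ohv_branch = Sequential([Identity(location_dim)], name="ohv")
    head_layers, d = _dense_dropout_head(feat_dim + location_dim, config.dropout_rate, rng)
    head_layers.append(_head_layer(d, config.n_classes, rng))
    net = FusionNetwork([img_branch, ohv_branch], Sequential(head_layers, name="head"))
    return ModelHandle(net, config, config.n_classes, "multimodal", rng)
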