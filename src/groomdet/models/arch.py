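"""Model configurations and the two architectures (3D-CNN and CRNN)."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .nn import (LSTM, Conv3D, Dense, Dropout, Flatten, FlattenFrames,
                 MaxPool3D, ReLU, Sequential)

#: per-architecture defaults (dropout, learning rate follow the published setup)
ARCH_DEFAULTS = {
    "cnn3d": dict(
        w=40,
        conv_widths=(64, 128, 256, 256, 512),
        fc_widths=(512, 256, 3),
        dropout=0.50,
        learning_rate=3e-5,
        double_blocks=(3, 4, 5),
        lstm_units=(),
    ),
    "crnn": dict(
        w=10,
        conv_widths=(32, 64, 128),
        fc_widths=(256, 128, 64, 32, 3),
        dropout=0.20,
        learning_rate=1e-4,
        double_blocks=(),
        lstm_units=(128, 128),
    ),
}

#: temporal/spatial pooling schedule of the 3D-CNN: early blocks keep
#: temporal resolution, later ones halve it.
CNN3D_POOLS = ((1, 2, 2), (2, 2, 2), (2, 2, 2), (2, 2, 2), (2, 2, 2))


class ConfigError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Architecture + training hyper-parameters.

    Fields left ``None`` are filled from :data:`ARCH_DEFAULTS` for the chosen
    architecture.
    """

    arch: str = "cnn3d"
    w: int | None = None
    conv_widths: tuple | None = None
    fc_widths: tuple | None = None
    dropout: float | None = None
    learning_rate: float | None = None
    seed: int = 0
    input_side: int = 128
    double_blocks: tuple | None = None
    lstm_units: tuple | None = None

    def __post_init__(self) -> None:
        if self.arch not in ARCH_DEFAULTS:
            raise ConfigError(f"unknown architecture {self.arch!r}")
        for name, default in ARCH_DEFAULTS[self.arch].items():
            if getattr(self, name) is None:
                setattr(self, name, default)
        for name in ("conv_widths", "fc_widths", "double_blocks", "lstm_units"):
            setattr(self, name, tuple(getattr(self, name)))
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.w < 1:
            raise ConfigError("half-window w must be >= 1")
        if self.fc_widths[-1] != 3:
            raise ConfigError("final fully-connected layer must have 3 units")
        if self.input_side < 2:
            raise ConfigError("input_side too small")

    @property
    def depth(self) -> int:
        return 2 * self.w + 1

    @property
    def input_shape(self) -> tuple[int, int, int, int]:
        return (self.depth, self.input_side, self.input_side, 1)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        return cls(**json.loads(text))


def build_cnn3d(config: ModelConfig) -> Sequential:
    """Five Conv3D(3,3,3)+MaxPool3D blocks, flatten, three Fc layers.

    Dropout after every pooling layer and between the first two Fc layers;
    ReLU everywhere except the 3-unit softmax head (softmax is applied by the
    loss / predictor).
    """
    if config.arch != "cnn3d":
        raise ConfigError("config.arch must be 'cnn3d'")
    if len(config.conv_widths) != len(CNN3D_POOLS):
        raise ConfigError(f"cnn3d needs {len(CNN3D_POOLS)} conv widths")
    if config.input_side // 2 ** len(CNN3D_POOLS) < 1:
        raise ConfigError(
            f"input_side {config.input_side} too small for "
            f"{len(CNN3D_POOLS)} spatial halvings (needs >= {2 ** len(CNN3D_POOLS)})"
        )
    rng = np.random.default_rng(config.seed)
    layers: list = []
    cin, d, s = 1, config.depth, config.input_side
    for bi, (width, pool) in enumerate(zip(config.conv_widths, CNN3D_POOLS), start=1):
        layers += [Conv3D(cin, width, (3, 3, 3), rng=rng, name=f"conv{bi}a"), ReLU()]
        if bi in config.double_blocks:
            layers += [Conv3D(width, width, (3, 3, 3), rng=rng, name=f"conv{bi}b"), ReLU()]
        layers += [MaxPool3D(pool), Dropout(config.dropout, rng.spawn(1)[0])]
        d, s, cin = d // pool[0], s // pool[1], width
        if d < 1 or s < 1:
            raise ConfigError(f"input collapsed to zero size at block {bi}")
    layers.append(Flatten())
    feat = d * s * s * cin
    for li, width in enumerate(config.fc_widths):
        layers.append(Dense(feat, width, rng=rng, name=f"fc{li + 1}"))
        if li < len(config.fc_widths) - 1:
            layers.append(ReLU())
        if li == 0 and len(config.fc_widths) > 1:
            layers.append(Dropout(config.dropout, rng.spawn(1)[0]))
        feat = width
    return Sequential(layers)


def build_crnn(config: ModelConfig) -> Sequential:
    """Three per-frame 2D conv blocks, two LSTM layers, five Fc layers.

    The 2D feature extractor is shared across time via (1, 3, 3) kernels and
    (1, 2, 2) pooling.  Dropout after each conv block and between Fc layers.
    """
    if config.arch != "crnn":
        raise ConfigError("config.arch must be 'crnn'")
    n_blocks = len(config.conv_widths)
    if config.input_side // 2 ** n_blocks < 1:
        raise ConfigError(
            f"input_side {config.input_side} too small for {n_blocks} spatial halvings"
        )
    if len(config.lstm_units) != 2:
        raise ConfigError("crnn needs exactly two recurrent layers")
    rng = np.random.default_rng(config.seed)
    layers: list = []
    cin, s = 1, config.input_side
    for bi, width in enumerate(config.conv_widths, start=1):
        layers += [
            Conv3D(cin, width, (1, 3, 3), rng=rng, name=f"conv{bi}"),
            ReLU(),
            MaxPool3D((1, 2, 2)),
            Dropout(config.dropout, rng.spawn(1)[0]),
        ]
        cin, s = width, s // 2
        if s < 1:
            raise ConfigError(f"input collapsed to zero size at block {bi}")
    layers.append(FlattenFrames())
    feat = s * s * cin
    u1, u2 = config.lstm_units
    layers.append(LSTM(feat, u1, return_sequences=True, rng=rng, name="lstm1"))
    layers.append(LSTM(u1, u2, return_sequences=False, rng=rng, name="lstm2"))
    feat = u2
    for li, width in enumerate(config.fc_widths):
        layers.append(Dense(feat, width, rng=rng, name=f"fc{li + 1}"))
        if li < len(config.fc_widths) - 1:
            layers += [ReLU(), Dropout(config.dropout, rng.spawn(1)[0])]
        feat = width
    return Sequential(layers)


def build_model(config: ModelConfig) -> Sequential:
    return build_cnn3d(config) if config.arch == "cnn3d" else build_crnn(config)
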