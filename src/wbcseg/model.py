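"""Three-level residual UNet for WBC foreground/background segmentation.

The contracting ("developing") path holds three residual convolution blocks
of 112, 224 and 448 filters, each followed by 2x2 max pooling; a residual
bottleneck sits below the third pooling.  The expansive path mirrors it with
three levels of nearest-neighbour x2 upsampling, skip concatenation, dropout
and residual convolution at widths 224, 122 and 122 (taken literally from
the source design; ``decoder_as_printed=False`` switches to 224/112/112).
A 1x1 convolution with a sigmoid yields one per-pixel foreground
probability map at input resolution.  ``width_multiplier`` scales every
filter count so the same topology trains at desk scale.

A classification variant reuses the contracting path as a backbone and
appends flatten -> dropout -> dense(n_classes) -> softmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    Dropout,
    Layer,
    Linear,
    MaxPool2x2,
    ReLU,
    UpsampleNearest2x,
)

__all__ = [
    "ModelConfig",
    "NetworkSummary",
    "ResidualBlock",
    "SegmentationUNet",
    "ClassificationNet",
    "build_segmentation_network",
    "build_classification_head",
    "predict_proba",
    "count_parameters",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; fully determines the network topology."""

    input_side: int = 224
    input_channels: int = 3
    encoder_filters: tuple[int, int, int] = (112, 224, 448)
    decoder_filters: tuple[int, int, int] = (224, 122, 122)
    dropout_rate: float = 0.2
    width_multiplier: float = 1.0
    use_residual_blocks: bool = True
    decoder_as_printed: bool = True

    def __post_init__(self) -> None:
        if self.input_side % 8 != 0:
            raise ValueError(
                "input_side must be divisible by 8 (three 2x2 poolings)"
            )
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")

    def scaled_encoder_filters(self) -> tuple[int, int, int]:
        return tuple(
            max(1, int(round(f * self.width_multiplier)))
            for f in self.encoder_filters
        )

    def scaled_decoder_filters(self) -> tuple[int, int, int]:
        base = (
            self.decoder_filters
            if self.decoder_as_printed
            else (224, 112, 112)
        )
        return tuple(
            max(1, int(round(f * self.width_multiplier))) for f in base
        )

    def to_dict(self) -> dict:
        return {
            "input_side": self.input_side,
            "input_channels": self.input_channels,
            "encoder_filters": list(self.encoder_filters),
            "decoder_filters": list(self.decoder_filters),
            "dropout_rate": self.dropout_rate,
            "width_multiplier": self.width_multiplier,
            "use_residual_blocks": self.use_residual_blocks,
            "decoder_as_printed": self.decoder_as_printed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["encoder_filters"] = tuple(d["encoder_filters"])
        d["decoder_filters"] = tuple(d["decoder_filters"])
        return cls(**d)


@dataclass(frozen=True)
class NetworkSummary:
    total_params: int
    trainable_params: int
    nontrainable_params: int
    rows: tuple[tuple[str, str, int], ...]  # (name, output shape, params)

    def __post_init__(self) -> None:
        if self.total_params != self.trainable_params + self.nontrainable_params:
            raise ValueError("total must equal trainable + nontrainable")

    def format(self) -> str:
        lines = [f"{'Layer type':<24}{'Output':<24}{'Parameter':>12}"]
        for name, shape, n in self.rows:
            lines.append(f"{name:<24}{shape:<24}{n:>12,}")
        lines.append(f"Total params: {self.total_params:,}")
        lines.append(f"Trainable params: {self.trainable_params:,}")
        lines.append(f"Nontrainable params: {self.nontrainable_params:,}")
        return "\n".join(lines)


class ResidualBlock(Layer):
    """conv3x3-BN-ReLU-conv3x3-BN with an identity/1x1-projection shortcut.

    When channel counts differ the shortcut is a bias-free 1x1 convolution
    followed by batch normalization.  ``residual=False`` drops the shortcut,
    leaving a plain double-convolution block.
    """

    def __init__(
        self,
        cin: int,
        cout: int,
        rng: np.random.Generator,
        residual: bool = True,
    ) -> None:
        super().__init__()
        self.cin, self.cout = cin, cout
        self.residual = residual
        self.conv1 = Conv2d(cin, cout, 3, rng)
        self.bn1 = BatchNorm2d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, rng)
        self.bn2 = BatchNorm2d(cout)
        self.relu_out = ReLU()
        self.proj = None
        self.bn_proj = None
        if residual and cin != cout:
            self.proj = Conv2d(cin, cout, 1, rng, bias=False)
            self.bn_proj = BatchNorm2d(cout)

    def sublayers(self) -> list[Layer]:
        out = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.proj is not None:
            out += [self.proj, self.bn_proj]
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = self.relu1.forward(
            self.bn1.forward(self.conv1.forward(x, training), training), training
        )
        h = self.bn2.forward(self.conv2.forward(h, training), training)
        if self.residual:
            if self.proj is not None:
                shortcut = self.bn_proj.forward(
                    self.proj.forward(x, training), training
                )
            else:
                shortcut = x
            h = h + shortcut
        return self.relu_out.forward(h, training)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dh = self.relu_out.backward(dout)
        dx = self.conv1.backward(
            self.bn1.backward(
                self.relu1.backward(self.conv2.backward(self.bn2.backward(dh)))
            )
        )
        if self.residual:
            if self.proj is not None:
                dx = dx + self.proj.backward(self.bn_proj.backward(dh))
            else:
                dx = dx + dh
        return dx

    def n_trainable(self) -> int:
        return sum(l.n_trainable() for l in self.sublayers())

    def n_nontrainable(self) -> int:
        return sum(l.n_nontrainable() for l in self.sublayers())


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SegmentationUNet:
    """The residual encoder-decoder with explicit skip bookkeeping."""

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(seed + 1)
        f1, f2, f3 = config.scaled_encoder_filters()
        d1, d2, d3 = config.scaled_decoder_filters()
        res = config.use_residual_blocks
        dr = config.dropout_rate

        self.enc1 = ResidualBlock(config.input_channels, f1, rng, res)
        self.pool1 = MaxPool2x2()
        self.enc2 = ResidualBlock(f1, f2, rng, res)
        self.pool2 = MaxPool2x2()
        self.enc3 = ResidualBlock(f2, f3, rng, res)
        self.pool3 = MaxPool2x2()
        self.bottleneck = ResidualBlock(f3, f3, rng, res)

        self.up1 = UpsampleNearest2x()
        self.drop1 = Dropout(dr, self._dropout_rng)
        self.dec1 = ResidualBlock(f3 + f3, d1, rng, res)
        self.up2 = UpsampleNearest2x()
        self.drop2 = Dropout(dr, self._dropout_rng)
        self.dec2 = ResidualBlock(d1 + f2, d2, rng, res)
        self.up3 = UpsampleNearest2x()
        self.drop3 = Dropout(dr, self._dropout_rng)
        self.dec3 = ResidualBlock(d2 + f1, d3, rng, res)
        self.head = Conv2d(d3, 1, 1, rng)
        self._enc_channels = (f1, f2, f3)
        self._dec_channels = (d1, d2, d3)

    # -- structural access -------------------------------------------------
    def blocks(self) -> list[tuple[str, Layer]]:
        return [
            ("enc_block_1", self.enc1),
            ("max_pool_1", self.pool1),
            ("enc_block_2", self.enc2),
            ("max_pool_2", self.pool2),
            ("enc_block_3", self.enc3),
            ("max_pool_3", self.pool3),
            ("bottleneck", self.bottleneck),
            ("up_concat_1", self.up1),
            ("dec_block_1", self.dec1),
            ("up_concat_2", self.up2),
            ("dec_block_2", self.dec2),
            ("up_concat_3", self.up3),
            ("dec_block_3", self.dec3),
            ("sigmoid_head_1x1", self.head),
        ]

    def all_layers(self) -> list[Layer]:
        out: list[Layer] = []
        for _, blk in self.blocks():
            if isinstance(blk, ResidualBlock):
                out.extend(blk.sublayers())
            else:
                out.append(blk)
        return out

    def encoder_blocks(self) -> list[ResidualBlock]:
        return [self.enc1, self.enc2, self.enc3]

    def set_dropout_seed(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        for d in (self.drop1, self.drop2, self.drop3):
            d.rng = rng

    # -- computation -------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.config.input_channels:
            raise ValueError(
                f"expected (N, {self.config.input_channels}, H, W) input, "
                f"got {x.shape}"
            )
        if x.shape[2] % 8 or x.shape[3] % 8:
            raise ValueError("spatial dimensions must be divisible by 8")
        s1 = self.enc1.forward(x, training)
        s2 = self.enc2.forward(self.pool1.forward(s1, training), training)
        s3 = self.enc3.forward(self.pool2.forward(s2, training), training)
        b = self.bottleneck.forward(self.pool3.forward(s3, training), training)

        u = self.up1.forward(b, training)
        u = self.drop1.forward(np.concatenate([u, s3], axis=1), training)
        u = self.dec1.forward(u, training)
        u = self.up2.forward(u, training)
        u = self.drop2.forward(np.concatenate([u, s2], axis=1), training)
        u = self.dec2.forward(u, training)
        u = self.up3.forward(u, training)
        u = self.drop3.forward(np.concatenate([u, s1], axis=1), training)
        u = self.dec3.forward(u, training)
        self._prob = _sigmoid(self.head.forward(u, training))
        return self._prob

    def backward(self, dprob: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the output probability map."""
        dz = dprob * self._prob * (1.0 - self._prob)  # through the sigmoid
        du = self.head.backward(dz)
        f1, f2, f3 = self._enc_channels
        d1, d2, _ = self._dec_channels

        du = self.drop3.backward(self.dec3.backward(du))
        du, ds1 = du[:, :d2], du[:, d2:]
        du = self.up3.backward(du)
        du = self.drop2.backward(self.dec2.backward(du))
        du, ds2 = du[:, :d1], du[:, d1:]
        du = self.up2.backward(du)
        du = self.drop1.backward(self.dec1.backward(du))
        du, ds3 = du[:, :f3], du[:, f3:]
        db = self.up1.backward(du)

        ds3 = ds3 + self.pool3.backward(self.bottleneck.backward(db))
        ds2 = ds2 + self.pool2.backward(self.enc3.backward(ds3))
        ds1 = ds1 + self.pool1.backward(self.enc2.backward(ds2))
        self.enc1.backward(ds1)


class ClassificationNet:
    """Contracting-path backbone + flatten -> dropout -> dense -> softmax."""

    def __init__(self, config: ModelConfig, n_classes: int = 4, seed: int = 0) -> None:
        if n_classes < 2:
            raise ValueError("n_classes must be at least 2")
        self.config = config
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)
        f1, f2, f3 = config.scaled_encoder_filters()
        res = config.use_residual_blocks
        self.enc1 = ResidualBlock(config.input_channels, f1, rng, res)
        self.pool1 = MaxPool2x2()
        self.enc2 = ResidualBlock(f1, f2, rng, res)
        self.pool2 = MaxPool2x2()
        self.enc3 = ResidualBlock(f2, f3, rng, res)
        self.pool3 = MaxPool2x2()
        side = config.input_side // 8
        self.flat_dim = f3 * side * side
        self.dropout = Dropout(config.dropout_rate, np.random.default_rng(seed + 1))
        self.dense = Linear(self.flat_dim, n_classes, rng)

    def blocks(self) -> list[tuple[str, Layer]]:
        return [
            ("enc_block_1", self.enc1),
            ("max_pool_1", self.pool1),
            ("enc_block_2", self.enc2),
            ("max_pool_2", self.pool2),
            ("enc_block_3", self.enc3),
            ("max_pool_3", self.pool3),
            ("flatten", Layer()),
            ("dropout", self.dropout),
            ("dense_softmax", self.dense),
        ]

    def all_layers(self) -> list[Layer]:
        out: list[Layer] = []
        for blk in (self.enc1, self.enc2, self.enc3):
            out.extend(blk.sublayers())
        out.append(self.dense)
        return out

    def encoder_blocks(self) -> list[ResidualBlock]:
        return [self.enc1, self.enc2, self.enc3]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = self.pool1.forward(self.enc1.forward(x, training), training)
        h = self.pool2.forward(self.enc2.forward(h, training), training)
        h = self.pool3.forward(self.enc3.forward(h, training), training)
        h = h.reshape(h.shape[0], -1)
        h = self.dropout.forward(h, training)
        logits = self.dense.forward(h, training)
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True)


def build_segmentation_network(config: ModelConfig, seed: int = 0) -> SegmentationUNet:
    """Construct the residual UNet; raises on an invalid configuration."""
    return SegmentationUNet(config, seed=seed)


def build_classification_head(
    config: ModelConfig, n_classes: int = 4, seed: int = 0
) -> ClassificationNet:
    return ClassificationNet(config, n_classes=n_classes, seed=seed)


def predict_proba(network: SegmentationUNet, batch: np.ndarray) -> np.ndarray:
    """Per-pixel foreground probabilities in (0,1); dropout disabled."""
    return network.forward(np.asarray(batch, dtype=np.float64), training=False)


def _output_shape(name: str, side: int, enc, dec) -> str:
    f1, f2, f3 = enc
    d1, d2, d3 = dec
    table = {
        "enc_block_1": (f1, side),
        "max_pool_1": (f1, side // 2),
        "enc_block_2": (f2, side // 2),
        "max_pool_2": (f2, side // 4),
        "enc_block_3": (f3, side // 4),
        "max_pool_3": (f3, side // 8),
        "bottleneck": (f3, side // 8),
        "up_concat_1": (2 * f3, side // 4),
        "dec_block_1": (d1, side // 4),
        "up_concat_2": (d1 + f2, side // 2),
        "dec_block_2": (d2, side // 2),
        "up_concat_3": (d2 + f1, side),
        "dec_block_3": (d3, side),
        "sigmoid_head_1x1": (1, side),
    }
    if name in table:
        c, s = table[name]
        return f"(N, {s}, {s}, {c})"
    return "(N, ...)"


def count_parameters(network) -> NetworkSummary:
    """Exact parameter tallies; BN running statistics count as nontrainable."""
    rows = []
    trainable = 0
    nontrainable = 0
    enc = getattr(network, "_enc_channels", None)
    dec = getattr(network, "_dec_channels", None)
    side = network.config.input_side
    for name, blk in network.blocks():
        n_tr = blk.n_trainable()
        n_non = blk.n_nontrainable()
        trainable += n_tr
        nontrainable += n_non
        if enc is not None and dec is not None:
            shape = _output_shape(name, side, enc, dec)
        else:
            shape = "(N, ...)"
        rows.append((name, shape, n_tr + n_non))
    return NetworkSummary(
        total_params=trainable + nontrainable,
        trainable_params=trainable,
        nontrainable_params=nontrainable,
        rows=tuple(rows),
    )
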