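"""The densely connected pseudo-3D (P3D) video classifier.

A pseudo-3D convolution factorizes a 3D spatio-temporal convolution into a
spatial (1x3x3) and a temporal (3x1x1) convolution.  Each dense block
concatenates (channel-wise, ``(+)``) its input with the outputs of the two
convolutional stages and pools:

    m_{p+1} = Max[ Conv_t(Conv_s(m_p) (+) m_p) (+) (Conv_s(m_p) (+) m_p) ]

where Conv_s / Conv_t are batch-norm -> ReLU -> convolution stages with k
(the growth rate) output channels, and Max is 2x2x2 stride-2 max pooling,
so a block maps c channels to c + 2k and halves every extent.

The full network: a 1x7x7 stride-2 spatial stem and a 9x1x1 stride-3
temporal stem, five dense blocks, a 3x1x1 unpadded mid convolution between
blocks 2 and 3 that trims the time axis so time and space extents match
(120 -> 40 -> 20 -> 10 -> 8 = 64/2/2/2/2... the shape trace is validated at
build time), dropout, a fully connected layer and softmax over 2 classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import (
    BatchNorm3d, Conv3d, Dropout, Flatten, Layer, Linear, MaxPool3d, Param,
    ReLU, softmax,
)

__all__ = ["NetworkConfig", "DenseP3DBlock", "Network", "build_network"]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters; defaults mirror the full-scale model."""

    in_channels: int = 2
    n_frames: int = 120
    height: int = 64
    width: int = 64
    growth_rate: int = 8
    stem_spatial_channels: int = 16
    stem_temporal_channels: int = 16
    stem_spatial_kernel: tuple = (1, 7, 7)
    stem_spatial_stride: tuple = (1, 2, 2)
    stem_temporal_kernel: tuple = (9, 1, 1)
    stem_temporal_stride: tuple = (3, 1, 1)
    n_dense_blocks: int = 5
    mid_conv_after: int | None = 2  # insert 3x1x1 unpadded conv after this block
    dropout: float = 0.5
    n_classes: int = 2

    @classmethod
    def desk_scale(cls) -> "NetworkConfig":
        """Reduced profile for 2 x 24 x 16 x 16 candidate videos.

        The temporal stem (9x1x1, stride 3, padding 4) maps 24 -> 8 frames
        and the spatial stem halves 16 -> 8, so three dense blocks reach
        1x1x1 without a mid convolution.
        """
        return cls(n_frames=24, height=16, width=16, growth_rate=8,
                   stem_spatial_channels=8, stem_temporal_channels=8,
                   n_dense_blocks=3, mid_conv_after=None)


class _ConvStage(Layer):
    """Batch norm -> ReLU -> convolution, in that order."""

    def __init__(self, in_channels: int, out_channels: int, kernel, padding):
        self.bn = BatchNorm3d(in_channels)
        self.relu = ReLU()
        self.conv = Conv3d(in_channels, out_channels, kernel, stride=1,
                           padding=padding)

    def params(self):
        return self.bn.params() + self.conv.params()

    def set_mode(self, train: bool):
        self.bn.train_mode = train

    def forward(self, x):
        return self.conv(self.relu(self.bn(x)))

    def backward(self, dy):
        return self.bn.backward(self.relu.backward(self.conv.backward(dy)))


class DenseP3DBlock(Layer):
    """One densely connected spatio-temporal convolution block."""

    def __init__(self, in_channels: int, growth_rate: int):
        self.in_channels = in_channels
        self.k = growth_rate
        self.conv_s = _ConvStage(in_channels, growth_rate, (1, 3, 3), (0, 1, 1))
        self.conv_t = _ConvStage(in_channels + growth_rate, growth_rate,
                                 (3, 1, 1), (1, 0, 0))
        self.pool = MaxPool3d()

    @property
    def out_channels(self) -> int:
        return self.in_channels + 2 * self.k

    def params(self):
        return self.conv_s.params() + self.conv_t.params()

    def set_mode(self, train: bool):
        self.conv_s.set_mode(train)
        self.conv_t.set_mode(train)

    def out_shape(self, shape):
        t, h, w = shape
        if min(t, h, w) < 2:
            raise ValueError(f"extent {shape} is not poolable")
        return (t // 2, h // 2, w // 2)

    def forward(self, x):
        s = self.conv_s(x)
        u = np.concatenate([s, x], axis=1)
        t = self.conv_t(u)
        v = np.concatenate([t, u], axis=1)
        return self.pool(v)

    def backward(self, dy):
        k = self.k
        dv = self.pool.backward(dy)
        dt, du = dv[:, :k], dv[:, k:].copy()
        du += self.conv_t.backward(dt)
        ds, dx = du[:, :k], du[:, k:].copy()
        dx += self.conv_s.backward(ds)
        return dx


class Network:
    """A sequential stack of layers with a recorded per-stage shape trace."""

    def __init__(self, layers: list, config: NetworkConfig, shape_trace: list):
        self.layers = layers
        self.config = config
        self.shape_trace = shape_trace  # [(stage name, (c, t, h, w) or (features,))]

    def params(self) -> list[Param]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def set_mode(self, train: bool):
        for layer in self.layers:
            layer.train_mode = train
            if hasattr(layer, "set_mode"):
                layer.set_mode(train)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch of videos (n, c, t, h, w)."""
        self.set_mode(train)
        x = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class probabilities (n, n_classes), evaluation mode."""
        x = np.asarray(x, dtype=np.float32)
        out = []
        for i in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size], train=False)))
        return np.concatenate(out) if out else np.zeros((0, self.config.n_classes))

    def initialize(self, rng: np.random.Generator, std: float = 0.05) -> None:
        """Truncated-normal (mean 0, ``std``, clipped at 2 std) for every
        convolution weight; zeros for the fully connected layer."""
        def trunc_normal(shape):
            v = rng.normal(0.0, std, size=shape)
            bad = np.abs(v) > 2 * std
            while bad.any():
                v[bad] = rng.normal(0.0, std, size=int(bad.sum()))
                bad = np.abs(v) > 2 * std
            return v.astype(np.float32)

        for layer in self.layers:
            stack = [layer]
            while stack:
                obj = stack.pop()
                if isinstance(obj, Conv3d):
                    obj.weight.value = trunc_normal(obj.weight.value.shape)
                    if obj.bias is not None:
                        obj.bias.value[:] = 0.0
                elif isinstance(obj, Linear):
                    obj.weight.value[:] = 0.0
                    obj.bias.value[:] = 0.0
                elif isinstance(obj, DenseP3DBlock):
                    stack.extend([obj.conv_s, obj.conv_t])
                elif isinstance(obj, _ConvStage):
                    stack.append(obj.conv)


def build_network(config: NetworkConfig | None = None) -> Network:
    """Assemble the classifier and verify its shape arithmetic.

    Raises ``ValueError`` naming the offending stage if any extent becomes
    non-positive or the final extent is not 1x1x1.
    """
    cfg = config or NetworkConfig()
    layers: list = []
    trace: list = []
    c = cfg.in_channels
    shape = (cfg.n_frames, cfg.height, cfg.width)
    trace.append(("input", (c,) + shape))

    def add_conv(name, conv, out_c):
        nonlocal c, shape
        try:
            shape = conv.out_shape(shape)
        except ValueError as e:
            raise ValueError(f"stage {name!r}: {e}") from e
        c = out_c
        layers.append(conv)
        trace.append((name, (c,) + shape))

    k = cfg.stem_spatial_kernel
    add_conv("stem_spatial",
             Conv3d(c, cfg.stem_spatial_channels, k, cfg.stem_spatial_stride,
                    tuple(kk // 2 for kk in k)),
             cfg.stem_spatial_channels)
    k = cfg.stem_temporal_kernel
    add_conv("stem_temporal",
             Conv3d(c, cfg.stem_temporal_channels, k, cfg.stem_temporal_stride,
                    tuple(kk // 2 for kk in k)),
             cfg.stem_temporal_channels)

    for b in range(cfg.n_dense_blocks):
        block = DenseP3DBlock(c, cfg.growth_rate)
        try:
            shape = block.out_shape(shape)
        except ValueError as e:
            raise ValueError(f"stage 'dense_block_{b + 1}': {e}") from e
        c = block.out_channels
        layers.append(block)
        trace.append((f"dense_block_{b + 1}", (c,) + shape))
        if cfg.mid_conv_after is not None and b + 1 == cfg.mid_conv_after:
            add_conv("mid_conv", Conv3d(c, c, (3, 1, 1), 1, 0), c)

    if shape != (1, 1, 1):
        raise ValueError(
            f"stage 'head': extent after the last dense block is {shape}, "
            "expected (1, 1, 1); adjust the architecture to the input size")
    layers.append(Flatten())
    layers.append(Dropout(cfg.dropout))
    layers.append(Linear(c, cfg.n_classes))
    trace.append(("fc", (cfg.n_classes,)))
    return Network(layers, cfg, trace)
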