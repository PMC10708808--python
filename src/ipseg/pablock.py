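"""Position Attention Block (PABlock).

The block injects positional prior knowledge into a feature map by

1. average-pooling the map separately over the width axis (keeping per-row
   context) and over the height axis (keeping per-column context),
2. fusing the two directional descriptors with a length-preserving 1D
   convolution + normalization + ReLU,
3. splitting the fused descriptor back into height and width parts and
   compressing each by an adaptive average pool with ratio ``r``,
4. concatenating a sinusoidal positional encoding onto the compressed
   descriptor and restoring the full extent (linear upscale, 1-wide
   convolutions, normalization, ReLU),
5. replicating each restored vector across the orthogonal axis, summing the
   two directional maps, and gating the input residually:
   ``Y = X + X * sigmoid(conv(O_h + O_w))``.

The sinusoidal encoding follows the sequence-model convention with base 1000:
row i (1-based) of the d-row table holds ``sin(p / base^{i/d})`` for even i
and ``cos(p / base^{(i-1)/d})`` for odd i, at each position p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import functional as F
from .nn.autograd import Tensor

__all__ = [
    "DirectionalDescriptor",
    "PositionalEncoding",
    "PABlockConfig",
    "pool_over_width",
    "pool_over_height",
    "split_descriptor",
    "compress",
    "compressed_length",
    "sinusoidal_encoding",
    "PABlock",
    "SegmentationHead",
]


@dataclass
class DirectionalDescriptor:
    """Per-direction pooled context: ``values`` is channels x length."""

    direction: str  # "height" | "width" | "fused"
    values: np.ndarray

    def __post_init__(self):
        if self.direction not in ("height", "width", "fused"):
            raise ValueError(f"unknown direction {self.direction!r}")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("descriptor values must be (channels, length)")

    @property
    def length(self) -> int:
        return self.values.shape[1]


@dataclass
class PositionalEncoding:
    """Sinusoidal table: ``values`` is d x length, all entries in [-1, 1]."""

    d: int
    base: float
    values: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class PABlockConfig:
    r: int = 64          # spatial compression ratio
    d: int = 512         # positional-encoding rows
    base: float = 1000.0  # encoding frequency base
    gate: str = "sigmoid"

    def __post_init__(self):
        if self.r < 1:
            raise ValueError("compression ratio r must be >= 1")
        if self.d < 2:
            raise ValueError("encoding dimension d must be >= 2")
        if self.gate != "sigmoid":
            raise ValueError("only the sigmoid gate is supported")


def _as_chw(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("expected a (C, H, W) feature map")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map contains non-finite values")
    return x


def pool_over_width(x: np.ndarray) -> DirectionalDescriptor:
    """Width-oriented average pooling: entry (c,h) = mean_w X[c,h,w]."""
    return DirectionalDescriptor("height", _as_chw(x).mean(axis=2))


def pool_over_height(x: np.ndarray) -> DirectionalDescriptor:
    """Height-oriented average pooling: entry (c,w) = mean_h X[c,h,w]."""
    return DirectionalDescriptor("width", _as_chw(x).mean(axis=1))


def split_descriptor(z: DirectionalDescriptor, height: int, width: int
                     ) -> tuple[DirectionalDescriptor, DirectionalDescriptor]:
    """Partition a fused C x (H+W) descriptor into height and width parts."""
    if height < 1 or width < 1:
        raise ValueError("height and width must be >= 1")
    if z.length != height + width:
        raise ValueError(f"descriptor length {z.length} != H+W = {height + width}")
    return (DirectionalDescriptor("height", z.values[:, :height]),
            DirectionalDescriptor("width", z.values[:, height:]))


def compressed_length(length: int, r: int) -> int:
    return max(1, math.ceil(length / r))


def compress(z: DirectionalDescriptor, r: int) -> DirectionalDescriptor:
    """Adaptive average pooling to ceil(L/r) contiguous bins (floor 1)."""
    if r < 1:
        raise ValueError("compression ratio r must be >= 1")
    out = F.adaptive_avg_pool_1d(Tensor(z.values), compressed_length(z.length, r))
    return DirectionalDescriptor(z.direction, out.data)


def sinusoidal_encoding(length: int, d: int = 512, base: float = 1000.0
                        ) -> PositionalEncoding:
    """Sine/cosine relative positional-encoding table of shape (d, length)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if d < 2:
        raise ValueError("d must be >= 2")
    i = np.arange(1, d + 1, dtype=np.float64)[:, None]   # 1-based row index
    p = np.arange(length, dtype=np.float64)[None, :]
    even = i % 2 == 0
    exponent = np.where(even, i, i - 1.0) / d
    angle = p / base ** exponent
    values = np.where(even, np.sin(angle), np.cos(angle))
    return PositionalEncoding(d=d, base=base, values=values)


class _Restore(nn.Module):
    """Restore path for one direction: GUP (linear upscale, 1-wide conv,
    norm, ReLU) then a final 1-wide conv back to the feature channel count."""

    def __init__(self, channels: int, cfg: PABlockConfig, rng: np.random.Generator):
        super().__init__()
        self.gup_conv = nn.Conv1d(channels + cfg.d, channels, 1, rng)
        self.gup_norm = nn.BatchNorm1d(channels)
        self.out_conv = nn.Conv1d(channels, channels, 1, rng)

    def forward(self, pe: np.ndarray, z_down: Tensor, full_length: int) -> Tensor:
        n = z_down.shape[0]
        if pe.shape[1] != z_down.shape[2]:
            raise ValueError(f"encoding length {pe.shape[1]} != descriptor "
                             f"length {z_down.shape[2]}")
        pe_t = Tensor(np.broadcast_to(
            pe.astype(z_down.dtype), (n,) + pe.shape).copy())
        h = nn.concat([pe_t, z_down], axis=1)
        h = F.resize_linear_1d(h, full_length, axis=-1)
        h = nn.relu(self.gup_norm(self.gup_conv(h)))
        return self.out_conv(h)


class PABlock(nn.Module):
    """Residual position-attention block over (N, C, H, W) feature maps."""

    def __init__(self, channels: int, cfg: PABlockConfig, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        self.cfg = cfg
        self.fuse_conv = nn.Conv1d(channels, channels, 3, rng, padding=1)
        self.fuse_norm = nn.BatchNorm1d(channels)
        self.restore_h = _Restore(channels, cfg, rng)
        self.restore_w = _Restore(channels, cfg, rng)
        # small-scale init keeps the untrained gate near 0.5 (Y ~ 1.5 X)
        # while letting gradients reach every upstream parameter
        self.gate_conv = nn.Conv2d(channels, channels, 1, rng, gain=0.1)
        self._pe_cache: dict[int, np.ndarray] = {}

    def _encoding(self, length: int) -> np.ndarray:
        if length not in self._pe_cache:
            self._pe_cache[length] = sinusoidal_encoding(
                length, self.cfg.d, self.cfg.base).values.astype(np.float32)
        return self._pe_cache[length]

    def fuse(self, zh: Tensor, zw: Tensor) -> Tensor:
        """Concatenate directional descriptors and apply conv + norm + ReLU."""
        if zh.shape[1] != zw.shape[1]:
            raise ValueError("descriptor channel counts differ")
        z = nn.concat([zh, zw], axis=2)
        return nn.relu(self.fuse_norm(self.fuse_conv(z)))

    def directional_maps(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """The restored height- and width-direction maps, each (N, C, H, W);
        the height map is constant along width and vice versa (Expand)."""
        n, c, h, w = x.shape
        if h < 1 or w < 1:
            raise ValueError("spatial dims must be >= 1")
        zh = x.mean(axis=3)                       # (N, C, H)
        zw = x.mean(axis=2)                       # (N, C, W)
        z = self.fuse(zh, zw)                     # (N, C, H+W)
        zh_f = nn.narrow(z, 2, 0, h)
        zw_f = nn.narrow(z, 2, h, w)
        zh_d = F.adaptive_avg_pool_1d(zh_f, compressed_length(h, self.cfg.r))
        zw_d = F.adaptive_avg_pool_1d(zw_f, compressed_length(w, self.cfg.r))
        o_h = self.restore_h(self._encoding(zh_d.shape[2]), zh_d, h)
        o_w = self.restore_w(self._encoding(zw_d.shape[2]), zw_d, w)
        o_h = nn.expand(o_h.reshape((n, c, h, 1)), 3, w)
        o_w = nn.expand(o_w.reshape((n, c, 1, w)), 2, h)
        return o_h, o_w

    def attention_logits(self, x: Tensor) -> Tensor:
        """Pre-gate attention map A = conv(O_h + O_w), same shape as x."""
        o_h, o_w = self.directional_maps(x)
        return self.gate_conv(o_h + o_w)

    def forward(self, x: Tensor) -> Tensor:
        a = self.attention_logits(x)
        return x + x * nn.sigmoid(a)


class SegmentationHead(nn.Module):
    """Per-class score maps: 3x3 convolution then bilinear upscale."""

    def __init__(self, in_channels: int, n_classes: int, rng: np.random.Generator):
        super().__init__()
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        self.n_classes = n_classes
        self.conv = nn.Conv2d(in_channels, n_classes, 3, rng, padding=1)

    def forward(self, x: Tensor, out_size: tuple[int, int]) -> Tensor:
        oh, ow = out_size
        if oh < x.shape[2] or ow < x.shape[3]:
            raise ValueError("output size smaller than the feature map")
        scores = self.conv(x)
        if (oh, ow) == (x.shape[2], x.shape[3]):
            return scores
        return F.resize_bilinear(scores, oh, ow)
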