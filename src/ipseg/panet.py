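"""Per-scale Position Attention Network and multi-scale fusion.

Each pyramid rung is processed by its own PANet: a convolutional backbone,
an atrous-spatial-pyramid-pooling (ASPP) context module, three consecutive
PABlocks, and a segmentation head that restores the rung's own resolution.
The per-scale score maps are then fused at the base resolution:

    y = conv1x1(concat(y_1, y_2, ..., y_S))

where rungs above 1x are bilinearly downsampled to the base size first.  The
fusion convolution is initialized to average the scales, so a single-scale
model starts out exactly equal to its per-scale branch.

The ``tiny`` backbone is a three-stage strided CNN sized to run a 112x112
forward pass in well under a second on one CPU; ``resnet101`` builds the
standard bottleneck stack (no pretrained weights) for users who want the
full-scale architecture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import functional as F
from .nn.autograd import Tensor
from .pablock import PABlock, PABlockConfig, SegmentationHead

__all__ = [
    "BackboneConfig",
    "ASPPConfig",
    "PANetConfig",
    "MultiScalePrediction",
    "build_backbone",
    "ASPP",
    "ScaleBranch",
    "PANet",
]


@dataclass(frozen=True)
class BackboneConfig:
    name: str = "tiny"            # {"tiny", "resnet101"}
    output_stride: int = 8        # {8, 16}
    feature_channels: int = 32

    def __post_init__(self):
        if self.name not in ("tiny", "resnet101"):
            raise ValueError(f"unknown backbone {self.name!r}")
        if self.output_stride not in (8, 16):
            raise ValueError("output_stride must be 8 or 16")
        if self.feature_channels < 1:
            raise ValueError("feature_channels must be positive")


@dataclass(frozen=True)
class ASPPConfig:
    dilation_rates: tuple[int, ...] = (2, 4, 6)
    branch_channels: int = 32
    global_pooling_branch: bool = True

    def __post_init__(self):
        rates = self.dilation_rates
        if len(set(rates)) != len(rates) or any(r < 1 for r in rates):
            raise ValueError("dilation rates must be distinct positive ints")


@dataclass(frozen=True)
class PANetConfig:
    """Full architecture description (serialized with checkpoints)."""

    factors: tuple[float, ...] = (1.0, 2.0)
    n_classes: int = 2
    in_channels: int = 1
    backbone: BackboneConfig = BackboneConfig()
    aspp: ASPPConfig = ASPPConfig()
    pablock: PABlockConfig = PABlockConfig(d=64)
    n_pablocks: int = 3
    use_pablocks: bool = True
    share_scale_weights: bool = False

    def __post_init__(self):
        if not self.factors or self.factors[0] != 1:
            raise ValueError("factors must be nonempty and start at 1")
        if any(b <= a for a, b in zip(self.factors, self.factors[1:])):
            raise ValueError("factors must be strictly increasing")


@dataclass
class MultiScalePrediction:
    """Per-scale score maps plus the fused base-resolution map."""

    per_scale: list[tuple[float, np.ndarray]]
    fused: np.ndarray = field(repr=False)


def _conv_bn_relu(rng, in_ch, out_ch, k, **kw):
    return [nn.Conv2d(in_ch, out_ch, k, rng, bias=False, **kw),
            nn.BatchNorm2d(out_ch), _ReLU()]


class _ReLU(nn.Module):
    def forward(self, x):
        return nn.relu(x)


class TinyBackbone(nn.Module):
    """Three (or four, at output stride 16) strided conv-BN-ReLU stages."""

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator,
                 in_channels: int = 1):
        super().__init__()
        c = cfg.feature_channels
        widths = [max(8, c // 4), max(16, c // 2), c]
        if cfg.output_stride == 16:
            widths.append(c)
        steps = []
        prev = in_channels
        for w in widths:
            steps += _conv_bn_relu(rng, prev, w, 3, stride=2, padding=1)
            prev = w
        self.body = nn.Sequential(*steps)

    def forward(self, x: Tensor) -> Tensor:
        return self.body(x)


class Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, in_ch, planes, rng, *, stride=1, dilation=1):
        super().__init__()
        out_ch = planes * self.expansion
        self.main = nn.Sequential(
            *_conv_bn_relu(rng, in_ch, planes, 1),
            *_conv_bn_relu(rng, planes, planes, 3, stride=stride,
                           padding=dilation, dilation=dilation),
            nn.Conv2d(planes, out_ch, 1, rng, bias=False),
            nn.BatchNorm2d(out_ch))
        self.down = None
        if stride != 1 or in_ch != out_ch:
            self.down = nn.Sequential(
                nn.Conv2d(in_ch, out_ch, 1, rng, bias=False, stride=stride),
                nn.BatchNorm2d(out_ch))

    def forward(self, x):
        identity = x if self.down is None else self.down(x)
        return nn.relu(self.main(x) + identity)


class ResNetBackbone(nn.Module):
    """Standard bottleneck ResNet (101 = [3,4,23,3]) with dilation to reach
    the requested output stride.  Randomly initialized; no pretrained weights."""

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator,
                 in_channels: int = 1, blocks=(3, 4, 23, 3)):
        super().__init__()
        self.stem = nn.Sequential(*_conv_bn_relu(rng, in_channels, 64, 7,
                                                 stride=2, padding=3))
        # stage strides for output stride 16: (1,2,2,1-dilated); for 8: (1,2,1,1)
        strides = (1, 2, 2, 1) if cfg.output_stride == 16 else (1, 2, 1, 1)
        dilations = (1, 1, 1, 2) if cfg.output_stride == 16 else (1, 1, 2, 4)
        layers = []
        in_ch, planes = 64, 64
        for nblocks, st, dil in zip(blocks, strides, dilations):
            stage = [Bottleneck(in_ch, planes, rng, stride=st, dilation=dil)]
            in_ch = planes * Bottleneck.expansion
            stage += [Bottleneck(in_ch, planes, rng, dilation=dil)
                      for _ in range(nblocks - 1)]
            layers.append(nn.Sequential(*stage))
            planes *= 2
        self.stages = layers
        self.project = nn.Sequential(*_conv_bn_relu(
            rng, in_ch, cfg.feature_channels, 1))

    def forward(self, x):
        from .nn.autograd import transpose
        x = self.stem(x)
        # 2x average pool stands in for the usual stem max pool
        h2, w2 = -(-x.shape[2] // 2), -(-x.shape[3] // 2)
        x = F.adaptive_avg_pool_1d(x, w2)
        x = transpose(x, (0, 1, 3, 2))
        x = F.adaptive_avg_pool_1d(x, h2)
        x = transpose(x, (0, 1, 3, 2))
        for stage in self.stages:
            x = stage(x)
        return self.project(x)


def build_backbone(cfg: BackboneConfig, rng: np.random.Generator,
                   in_channels: int = 1) -> nn.Module:
    if cfg.name == "tiny":
        return TinyBackbone(cfg, rng, in_channels)
    return ResNetBackbone(cfg, rng, in_channels)


class _GlobalPoolBranch(nn.Module):
    """Global average pooling -> 1x1 conv-BN-ReLU -> broadcast back."""

    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, 1, rng, bias=False)
        self.norm = nn.BatchNorm2d(out_ch)

    def forward(self, x):
        n, c, h, w = x.shape
        g = x.mean(axis=(2, 3), keepdims=True)
        g = nn.relu(self.norm(self.conv(g)))
        g = nn.expand(g, 2, h)
        return nn.expand(g, 3, w)


class ASPP(nn.Module):
    """Atrous spatial pyramid pooling: parallel dilated 3x3 branches, a 1x1
    branch, an optional global-pooling branch, concatenated and projected."""

    def __init__(self, in_ch: int, cfg: ASPPConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        bc = cfg.branch_channels
        self.branch1x1 = nn.Sequential(*_conv_bn_relu(rng, in_ch, bc, 1))
        self.dilated = [nn.Sequential(*_conv_bn_relu(rng, in_ch, bc, 3,
                                                     padding=r, dilation=r))
                        for r in cfg.dilation_rates]
        self.global_branch = (_GlobalPoolBranch(in_ch, bc, rng)
                              if cfg.global_pooling_branch else None)
        n_branches = 1 + len(self.dilated) + (1 if self.global_branch else 0)
        self.project = nn.Sequential(*_conv_bn_relu(rng, n_branches * bc, bc, 1))

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        span = 2 * max(self.cfg.dilation_rates) + 1
        if span > h or span > w:
            raise ValueError(f"dilation span {span} exceeds feature extent "
                             f"{h}x{w}")
        branches = [self.branch1x1(x)] + [b(x) for b in self.dilated]
        if self.global_branch is not None:
            branches.append(self.global_branch(x))
        return self.project(nn.concat(branches, axis=1))


class ScaleBranch(nn.Module):
    """One pyramid rung: backbone -> ASPP -> n x PABlock -> head."""

    def __init__(self, cfg: PANetConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.backbone = build_backbone(cfg.backbone, rng, cfg.in_channels)
        self.aspp = ASPP(cfg.backbone.feature_channels, cfg.aspp, rng)
        bc = cfg.aspp.branch_channels
        self.pablocks = [PABlock(bc, cfg.pablock, rng)
                         for _ in range(cfg.n_pablocks)]
        self.head = SegmentationHead(bc, cfg.n_classes, rng)

    def features(self, x: Tensor, use_pablocks: bool = True) -> Tensor:
        f = self.aspp(self.backbone(x))
        if use_pablocks:
            for block in self.pablocks:
                f = block(f)
        return f

    def forward(self, x: Tensor, use_pablocks: bool | None = None) -> Tensor:
        use = self.cfg.use_pablocks if use_pablocks is None else use_pablocks
        f = self.features(x, use)
        return self.head(f, (x.shape[2], x.shape[3]))


class PANet(nn.Module):
    """Multi-scale position-attention segmentation network.

    ``forward`` takes the list of pyramid rung tensors (one (N, C, H_s, W_s)
    tensor per factor, ascending) and returns per-scale score maps plus the
    fused base-resolution map.
    """

    def __init__(self, cfg: PANetConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        if cfg.share_scale_weights:
            shared = ScaleBranch(cfg, rng)
            self.branches = [shared] * len(cfg.factors)
        else:
            self.branches = [ScaleBranch(cfg, rng) for _ in cfg.factors]
        s, k = len(cfg.factors), cfg.n_classes
        w = np.zeros((k, s * k, 1, 1), dtype=np.float32)
        for si in range(s):
            for ki in range(k):
                w[ki, si * k + ki, 0, 0] = 1.0 / s
        self.fuse_conv = nn.Conv2d(s * k, k, 1, rng)
        self.fuse_conv.weight.data = w  # scale-averaging initialization

    # -------------------------------------------------------------- forward
    def forward(self, rungs: list[Tensor]) -> tuple[list[Tensor], Tensor]:
        if len(rungs) != len(self.cfg.factors):
            raise ValueError(f"expected {len(self.cfg.factors)} pyramid rungs, "
                             f"got {len(rungs)}")
        per_scale = [branch(x) for branch, x in zip(self.branches, rungs)]
        fused = self.fuse(per_scale)
        return per_scale, fused

    def fuse(self, per_scale: list[Tensor]) -> Tensor:
        """Fusion: downsample to base resolution, concat, 1x1 convolution."""
        k = self.cfg.n_classes
        if any(p.shape[1] != k for p in per_scale):
            raise ValueError("per-scale class counts differ")
        base_h, base_w = per_scale[0].shape[2], per_scale[0].shape[3]
        aligned = [p if (p.shape[2], p.shape[3]) == (base_h, base_w)
                   else F.resize_bilinear(p, base_h, base_w)
                   for p in per_scale]
        return self.fuse_conv(nn.concat(aligned, axis=1))

    def baseline_forward(self, x: Tensor) -> Tensor:
        """The backbone+ASPP+head path of the base branch, PABlocks off."""
        return self.branches[0](x, use_pablocks=False)
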