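"""Model variants built from split-fusion convolution and channel/spatial attention.

Four variants share a 50-layer residual backbone:

* ``baseline`` — plain bottleneck blocks (1x1 -> 3x3 -> 1x1, shortcut).
* ``res_sp``   — the 3x3 stage replaced by a split convolution: a
  "representative" channel fraction goes through a grouped 3x3 plus a
  parallel pointwise 1x1 (summed), the "redundant" remainder through a
  cheap pointwise 1x1; branches are fused by a parameter-free pooled
  soft-attention weighted sum.
* ``res_cba``  — plain 3x3 stage plus a channel-then-spatial attention
  gate applied to the block output just before the residual addition.
* ``htrec``    — both modifications together:
  1x1 -> 3x3 split conv -> 1x1 -> attention -> residual addition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
    Tensor,
    concat,
)

VARIANTS = ("baseline", "res_sp", "res_cba", "htrec")
EXPANSION = 4


# --------------------------------------------------------------------- config
@dataclass
class ArchConfig:
    """Architectural hyperparameters for one model variant."""

    variant: str = "htrec"
    num_classes: int = 3
    input_size: int = 224
    stage_depths: Tuple[int, int, int, int] = (3, 4, 6, 3)
    spconv_alpha: float = 0.5
    spconv_groups: int = 2
    cbam_reduction: int = 16
    cbam_spatial_kernel: int = 7
    base_width: int = 64  # stem/stage-1 mid width; 64 is the full-size network

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.input_size < 32 or self.input_size % 32:
            raise ValueError("input_size must be a positive multiple of 32")
        depths = tuple(int(d) for d in self.stage_depths)
        if len(depths) != 4 or any(d < 1 for d in depths):
            raise ValueError("stage_depths must be 4 positive integers")
        self.stage_depths = depths
        if not (0.0 < self.spconv_alpha <= 1.0):
            raise ValueError("spconv_alpha must lie in (0, 1]")
        if self.spconv_groups < 1:
            raise ValueError("spconv_groups must be positive")
        if self.cbam_spatial_kernel < 1 or self.cbam_spatial_kernel % 2 == 0:
            raise ValueError("cbam_spatial_kernel must be odd and positive")
        if self.base_width < 4:
            raise ValueError("base_width must be >= 4")
        if self.uses_spconv:
            for w in self.stage_widths:
                rep = math.ceil(self.spconv_alpha * w)
                if rep % self.spconv_groups:
                    raise ValueError(
                        f"representative channels {rep} (width {w}) not divisible "
                        f"by spconv_groups={self.spconv_groups}"
                    )
        if self.uses_cbam:
            smallest = EXPANSION * self.base_width
            if self.cbam_reduction > smallest:
                raise ValueError(
                    f"cbam_reduction={self.cbam_reduction} exceeds the smallest "
                    f"attended channel count {smallest}"
                )

    @property
    def stage_widths(self) -> Tuple[int, int, int, int]:
        return tuple(self.base_width * (2 ** i) for i in range(4))

    @property
    def uses_spconv(self) -> bool:
        return self.variant in ("res_sp", "htrec")

    @property
    def uses_cbam(self) -> bool:
        return self.variant in ("res_cba", "htrec")


# ---------------------------------------------------------------- description
@dataclass
class LayerDescriptor:
    """One structural row driving both complexity counting and shape checks."""

    kind: str
    in_channels: int = 0
    out_channels: int = 0
    kernel: Tuple[int, int] = (1, 1)
    stride: int = 1
    groups: int = 1
    has_bias: bool = False
    affine: bool = True
    out_spatial: Tuple[int, int] = (1, 1)
    hidden: int = 0  # channel-attention bottleneck width
    name: str = ""

    KINDS = (
        "conv", "grouped_conv", "pointwise_conv", "batch_norm", "activation",
        "pool", "global_pool", "linear", "channel_attention",
        "spatial_attention", "add",
    )

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == "grouped_conv":
            if self.in_channels % self.groups or self.out_channels % self.groups:
                raise ValueError("groups must divide in_channels and out_channels")
        if self.kind == "pointwise_conv" and self.kernel != (1, 1):
            raise ValueError("pointwise_conv requires a 1x1 kernel")


@dataclass
class NetworkDescription:
    layers: List[LayerDescriptor] = field(default_factory=list)
    total_stages: int = 4

    def __iter__(self):
        return iter(self.layers)

    def __len__(self):
        return len(self.layers)


# ------------------------------------------------------------------ split conv
def split_channels(x: Tensor, alpha: float) -> Tuple[Tensor, Optional[Tensor]]:
    """Partition channels into a representative head and a redundant tail.

    The first ``ceil(alpha * C)`` channels (in index order) form the
    representative part; concatenating the two parts restores ``x``.
    With ``alpha == 1`` the redundant part is ``None``.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    c = x.shape[1]
    if alpha < 1.0 and c < 2:
        raise ValueError("need at least 2 channels to split when alpha < 1")
    rep = math.ceil(alpha * c)
    if rep >= c:
        return x, None
    return x[:, :rep], x[:, rep:]


def spconv_fuse(y_rep: Tensor, y_red: Tensor, return_weights: bool = False):
    """Parameter-free fusion: pooled per-channel statistics -> softmax weights.

    Each branch is reduced by global average pooling to a per-channel
    statistic; a softmax across the two statistics yields convex weights
    that blend the branches channel-wise.
    """
    if y_rep.shape != y_red.shape:
        raise ValueError(f"branch shapes differ: {y_rep.shape} vs {y_red.shape}")
    b, c = y_rep.shape[0], y_rep.shape[1]
    g_rep = y_rep.mean(axis=(2, 3))
    g_red = y_red.mean(axis=(2, 3))
    m = np.maximum(g_rep.data, g_red.data)  # detached shift for stability
    e_rep = (g_rep - m).exp()
    e_red = (g_red - m).exp()
    denom = e_rep + e_red
    w_rep = e_rep / denom
    w_red = e_red / denom
    out = y_rep * w_rep.reshape(b, c, 1, 1) + y_red * w_red.reshape(b, c, 1, 1)
    if return_weights:
        return out, (w_rep, w_red)
    return out


class SplitConv(Module):
    """3x3 stage replacement: grouped 3x3 + pointwise on the representative
    channels (summed, then batch-normed), pointwise on the redundant channels
    (batch-normed), fused by :func:`spconv_fuse`."""

    def __init__(self, in_channels: int, out_channels: int, stride: int = 1,
                 alpha: float = 0.5, groups: int = 2,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        rep = math.ceil(alpha * in_channels)
        red = in_channels - rep
        if rep % groups:
            raise ValueError(
                f"representative channels {rep} not divisible by groups={groups}"
            )
        self.alpha, self.rep, self.red, self.stride = alpha, rep, red, stride
        self.conv_rep3 = Conv2d(rep, out_channels, 3, stride=stride, padding=1,
                                groups=groups, bias=True, rng=rng)
        self.conv_rep1 = Conv2d(rep, out_channels, 1, stride=stride, bias=True, rng=rng)
        self.bn_rep = BatchNorm2d(out_channels)
        if red:
            self.conv_red = Conv2d(red, out_channels, 1, stride=stride, bias=True, rng=rng)
            self.bn_red = BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        x_rep, x_red = split_channels(x, self.alpha)
        y_rep = self.bn_rep(self.conv_rep3(x_rep) + self.conv_rep1(x_rep))
        if x_red is None:
            return y_rep
        y_red = self.bn_red(self.conv_red(x_red))
        return spconv_fuse(y_rep, y_red)


# ------------------------------------------------------------------- attention
class ChannelAttention(Module):
    """Shared-MLP channel gate from average- and max-pooled descriptors.

    The MLP is C -> C//r -> C with a rectifier between and no biases;
    gate = sigmoid(MLP(avg) + MLP(max) + logit_offset).  ``logit_offset``
    is a plain diagnostic constant (not a learned parameter) used to
    saturate the gate in equivalence tests.
    """

    def __init__(self, channels: int, reduction: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if reduction > channels:
            raise ValueError(f"reduction {reduction} exceeds channel count {channels}")
        hidden = channels // reduction
        if hidden < 1:
            raise ValueError("reduction leaves an empty MLP bottleneck")
        rng = rng or np.random.default_rng(0)
        from .nn import Parameter

        self.w1 = Parameter(rng.normal(0, np.sqrt(2.0 / channels), (channels, hidden)))
        self.w2 = Parameter(rng.normal(0, np.sqrt(2.0 / hidden), (hidden, channels)))
        self.channels, self.reduction, self.hidden = channels, reduction, hidden
        self.logit_offset = 0.0

    def _mlp(self, v: Tensor) -> Tensor:
        return (v @ self.w1).relu() @ self.w2

    def gate(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=(2, 3))
        mx = x.max(axis=(2, 3))
        logit = self._mlp(avg) + self._mlp(mx)
        if self.logit_offset:
            logit = logit + self.logit_offset
        b, c = x.shape[0], x.shape[1]
        return logit.sigmoid().reshape(b, c, 1, 1)

    def forward(self, x: Tensor) -> Tensor:
        return x * self.gate(x)


class SpatialAttention(Module):
    """Spatial gate: channel-wise mean/max maps -> k x k conv -> sigmoid."""

    def __init__(self, kernel: int = 7, rng: np.random.Generator | None = None):
        super().__init__()
        if kernel % 2 == 0 or kernel < 1:
            raise ValueError("spatial attention kernel must be odd and positive")
        self.conv = Conv2d(2, 1, kernel, padding=(kernel - 1) // 2, bias=True, rng=rng)
        self.kernel = kernel

    def gate(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        return self.conv(concat([avg, mx], axis=1)).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return x * self.gate(x)


class CBAM(Module):
    """Sequential channel-then-spatial multiplicative attention."""

    def __init__(self, channels: int, reduction: int, spatial_kernel: int = 7,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction, rng=rng)
        self.spatial = SpatialAttention(spatial_kernel, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.channel(x)
        return self.spatial(x)

    def saturate(self, offset: float = 40.0) -> None:
        """Force both gates to 1 (float32-exact) for equivalence checks."""
        self.channel.w1.data[:] = 0.0
        self.channel.w2.data[:] = 0.0
        self.channel.logit_offset = offset
        self.spatial.conv.weight.data[:] = 0.0
        self.spatial.conv.bias.data[:] = offset


# ------------------------------------------------------------------ bottleneck
class Bottleneck(Module):
    """Residual unit: 1x1 reduce -> 3x3 transform (plain or split) -> 1x1
    expand -> optional attention -> shortcut addition -> rectifier."""

    def __init__(self, cfg: ArchConfig, in_channels: int, mid_channels: int,
                 stride: int, rng: np.random.Generator | None = None):
        super().__init__()
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        out_channels = EXPANSION * mid_channels
        self.conv1 = Conv2d(in_channels, mid_channels, 1, rng=rng)
        self.bn1 = BatchNorm2d(mid_channels)
        if cfg.uses_spconv:
            self.mid = SplitConv(mid_channels, mid_channels, stride=stride,
                                 alpha=cfg.spconv_alpha, groups=cfg.spconv_groups,
                                 rng=rng)
        else:
            self.mid = Conv2d(mid_channels, mid_channels, 3, stride=stride,
                              padding=1, rng=rng)
        self.bn2 = BatchNorm2d(mid_channels)
        self.conv3 = Conv2d(mid_channels, out_channels, 1, rng=rng)
        self.bn3 = BatchNorm2d(out_channels)
        self.cbam = (
            CBAM(out_channels, cfg.cbam_reduction, cfg.cbam_spatial_kernel, rng=rng)
            if cfg.uses_cbam else None
        )
        if stride != 1 or in_channels != out_channels:
            self.proj = Conv2d(in_channels, out_channels, 1, stride=stride, rng=rng)
            self.bn_proj = BatchNorm2d(out_channels)
        else:
            self.proj = None
        self.in_channels, self.mid_channels = in_channels, mid_channels
        self.out_channels, self.stride = out_channels, stride

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.mid(y)).relu()
        y = self.bn3(self.conv3(y))
        if self.cbam is not None:
            y = self.cbam(y)
        shortcut = x if self.proj is None else self.bn_proj(self.proj(x))
        return (y + shortcut).relu()


# ----------------------------------------------------------------------- model
class HistoNet(Module):
    """Full classifier: stem -> 4 bottleneck stages -> pooled linear head."""

    def __init__(self, cfg: ArchConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        w0 = cfg.base_width
        self.stem_conv = Conv2d(3, w0, 7, stride=2, padding=3, rng=rng)
        self.stem_bn = BatchNorm2d(w0)
        self.stem_pool = MaxPool2d(3, 2, 1)
        blocks = []
        cin = w0
        for si, (width, depth) in enumerate(zip(cfg.stage_widths, cfg.stage_depths)):
            for b in range(depth):
                stride = 2 if (b == 0 and si > 0) else 1
                blocks.append(Bottleneck(cfg, cin, width, stride, rng=rng))
                cin = EXPANSION * width
        self.blocks = Sequential_(*blocks)
        self.pool = GlobalAvgPool()
        self.head = Linear(cin, cfg.num_classes, rng=rng)
        self.feature_channels = cin
        self.last_features: Optional[Tensor] = None

    def forward(self, x, capture_features: bool = False) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError("expected input of shape (batch, 3, H, W)")
        y = self.stem_bn(self.stem_conv(x)).relu()
        y = self.stem_pool(y)
        y = self.blocks(y)
        self.last_features = y if capture_features else None
        return self.head(self.pool(y))

    # ------------------------------------------------------------ description
    def describe(self, input_size: Optional[int] = None) -> NetworkDescription:
        cfg = self.cfg
        size = input_size or cfg.input_size
        d: List[LayerDescriptor] = []
        hw = size // 2
        w0 = cfg.base_width

        def conv_desc(kind, cin, cout, k, s, hw_out, groups=1, bias=False, name=""):
            d.append(LayerDescriptor(kind, cin, cout, (k, k), s, groups, bias,
                                     out_spatial=(hw_out, hw_out), name=name))

        conv_desc("conv", 3, w0, 7, 2, hw, name="stem.conv")
        d.append(LayerDescriptor("batch_norm", w0, w0, out_spatial=(hw, hw), name="stem.bn"))
        d.append(LayerDescriptor("activation", w0, w0, out_spatial=(hw, hw), name="stem.relu"))
        hw //= 2
        d.append(LayerDescriptor("pool", w0, w0, (3, 3), 2, out_spatial=(hw, hw), name="stem.pool"))

        for bi, blk in enumerate(self.blocks._order):
            n = f"block{bi}"
            cin, mid, cout, s = blk.in_channels, blk.mid_channels, blk.out_channels, blk.stride
            hw_out = hw // s
            conv_desc("pointwise_conv", cin, mid, 1, 1, hw, name=f"{n}.conv1")
            d.append(LayerDescriptor("batch_norm", mid, mid, out_spatial=(hw, hw), name=f"{n}.bn1"))
            d.append(LayerDescriptor("activation", mid, mid, out_spatial=(hw, hw), name=f"{n}.relu1"))
            if isinstance(blk.mid, SplitConv):
                sc = blk.mid
                conv_desc("grouped_conv", sc.rep, mid, 3, s, hw_out,
                          groups=sc.conv_rep3.groups, bias=True, name=f"{n}.sp.rep3")
                conv_desc("pointwise_conv", sc.rep, mid, 1, s, hw_out, bias=True,
                          name=f"{n}.sp.rep1")
                d.append(LayerDescriptor("batch_norm", mid, mid,
                                         out_spatial=(hw_out, hw_out), name=f"{n}.sp.bn_rep"))
                if sc.red:
                    conv_desc("pointwise_conv", sc.red, mid, 1, s, hw_out, bias=True,
                              name=f"{n}.sp.red1")
                    d.append(LayerDescriptor("batch_norm", mid, mid,
                                             out_spatial=(hw_out, hw_out), name=f"{n}.sp.bn_red"))
            else:
                conv_desc("conv", mid, mid, 3, s, hw_out, name=f"{n}.conv2")
            d.append(LayerDescriptor("batch_norm", mid, mid, out_spatial=(hw_out, hw_out), name=f"{n}.bn2"))
            d.append(LayerDescriptor("activation", mid, mid, out_spatial=(hw_out, hw_out), name=f"{n}.relu2"))
            conv_desc("pointwise_conv", mid, cout, 1, 1, hw_out, name=f"{n}.conv3")
            d.append(LayerDescriptor("batch_norm", cout, cout, out_spatial=(hw_out, hw_out), name=f"{n}.bn3"))
            if blk.cbam is not None:
                d.append(LayerDescriptor("channel_attention", cout, cout,
                                         out_spatial=(hw_out, hw_out),
                                         hidden=blk.cbam.channel.hidden, name=f"{n}.cbam.channel"))
                k = blk.cbam.spatial.kernel
                d.append(LayerDescriptor("spatial_attention", cout, 1, (k, k),
                                         has_bias=True, out_spatial=(hw_out, hw_out),
                                         name=f"{n}.cbam.spatial"))
            if blk.proj is not None:
                conv_desc("pointwise_conv", cin, cout, 1, s, hw_out, name=f"{n}.proj")
                d.append(LayerDescriptor("batch_norm", cout, cout,
                                         out_spatial=(hw_out, hw_out), name=f"{n}.bn_proj"))
            d.append(LayerDescriptor("add", cout, cout, out_spatial=(hw_out, hw_out), name=f"{n}.add"))
            d.append(LayerDescriptor("activation", cout, cout, out_spatial=(hw_out, hw_out), name=f"{n}.relu3"))
            hw = hw_out

        d.append(LayerDescriptor("global_pool", self.feature_channels,
                                 self.feature_channels, out_spatial=(1, 1), name="gap"))
        d.append(LayerDescriptor("linear", self.feature_channels, cfg.num_classes,
                                 has_bias=True, name="head"))
        # consecutive shape compatibility is enforced by construction above
        return NetworkDescription(layers=d, total_stages=4)


class Sequential_(Module):
    """Ordered container (kept separate from nn.Sequential to expose _order)."""

    def __init__(self, *mods: Module):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, f"b{i}", m)
        self._order = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self._order:
            x = m(x)
        return x


def build_network(cfg: ArchConfig, seed: int = 0) -> HistoNet:
    """Instantiate a variant; ``model.describe()`` yields the layer inventory
    that the complexity module counts, guaranteeing the two views agree."""
    return HistoNet(cfg, seed=seed)
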