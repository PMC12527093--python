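"""LMCSleepNet: a lightweight multi-channel sleep-staging network.

The network classifies one 30 s polysomnography epoch, presented as a
[3 channel x 200 time x 32 scale] Morlet scalogram stack, into the five AASM
stages (W, N1, N2, N3, REM).  Architecture:

* **MSDC stem** — three parallel 3x3 convolutions with dilation rates 1/2/3
  (stride 2, padding = dilation, 3->64 each, batch-norm each), fused by channel
  concatenation (192) and a 1x1 convolution back to 64 (+BN+ReLU).  Dilation
  enlarges the receptive field at constant parameter cost.
* **Depthwise-separable ResNet18 body** — four stages of two residual basic
  blocks (widths 64/128/256/512); every 3x3 convolution is factorised into a
  per-channel depthwise 3x3 plus a 1x1 pointwise channel mixer, each followed
  by batch-norm.  Stages 2-4 downsample with stride 2 and a 1x1 projection
  shortcut.
* **CBAM** — channel attention (shared two-layer bottleneck MLP over global
  avg/max pooled descriptors, reduction 16) followed by spatial attention
  (7x7 convolution over channel-wise mean/max maps), applied once after the
  last stage.
* **Head** — global average pool -> dropout(0.5) -> fully connected 512->5
  -> softmax.

Ablation flags (``use_msdc``, ``use_dsc``, ``use_cbam``) recover the plain
ResNet18 baseline and its intermediate variants; with everything off and a
1000-way head the builder reproduces the standard ImageNet ResNet18 exactly
(11,689,512 parameters).  The fully pinned default has 1,492,840.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .nn import (BatchNorm2d, Conv2d, DepthwiseConv2d, Dropout,
                 GlobalAvgPool2d, Linear, MaxPool2d, Module, Parameter, ReLU,
                 Sequential, softmax)

__all__ = [
    "ModelConfig",
    "Prediction",
    "LayerRecord",
    "NetworkDescription",
    "LMCSleepNet",
    "MSDCStem",
    "DSCConv",
    "BasicBlock",
    "ChannelAttention",
    "SpatialAttention",
    "CBAM",
    "build_network",
    "describe",
    "count_parameters",
]

ABLATION_VARIANTS = ("resnet18", "+cbam", "+cbam+dsc", "full")


@dataclass
class ModelConfig:
    """Pinned hyper-parameters of the layer graph."""

    in_channels: int = 3
    dilations: tuple = (1, 2, 3)
    stem_branch_channels: int = 64
    stem_fused_channels: int = 64
    stage_widths: tuple = (64, 128, 256, 512)
    blocks_per_stage: int = 2
    use_dsc: bool = True
    use_cbam: bool = True
    use_msdc: bool = True
    msdc_fusion: str = "concat"  # "concat" | "add"
    cbam_reduction: int = 16
    spatial_kernel: int = 7
    num_classes: int = 5
    dropout_p: float = 0.5

    def validate(self) -> None:
        if list(self.dilations) != sorted(set(self.dilations)) or min(self.dilations) < 1:
            raise ValueError("dilations must be strictly increasing positive integers")
        if self.use_cbam and self.stage_widths[-1] % self.cbam_reduction != 0:
            raise ValueError(
                f"cbam_reduction {self.cbam_reduction} must divide final stage "
                f"width {self.stage_widths[-1]}")
        if self.spatial_kernel % 2 != 1:
            raise ValueError("spatial_kernel must be odd")
        if self.msdc_fusion not in ("concat", "add"):
            raise ValueError(f"unknown msdc_fusion {self.msdc_fusion!r}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")

    @classmethod
    def for_variant(cls, variant: str, **overrides) -> "ModelConfig":
        """Ablation-grid presets: resnet18, +cbam, +cbam+dsc, full."""
        flags = {
            "resnet18": dict(use_cbam=False, use_dsc=False, use_msdc=False),
            "+cbam": dict(use_cbam=True, use_dsc=False, use_msdc=False),
            "+cbam+dsc": dict(use_cbam=True, use_dsc=True, use_msdc=False),
            "full": dict(use_cbam=True, use_dsc=True, use_msdc=True),
        }
        if variant not in flags:
            raise ValueError(
                f"unknown variant {variant!r}; expected one of {ABLATION_VARIANTS}")
        return replace(cls(**overrides), **flags[variant])


@dataclass
class Prediction:
    """Softmax output for one epoch."""

    probabilities: np.ndarray
    logits: np.ndarray

    @property
    def label(self) -> int:
        return int(np.argmax(self.probabilities))


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


class DSCConv(Sequential):
    """Depthwise-separable 3x3 convolution: depthwise (+BN) then 1x1 pointwise (+BN).

    The depthwise stage filters each channel independently (no channel mixing);
    the pointwise stage mixes channels only.  The stride lives on the depthwise
    stage.
    """

    def __init__(self, in_channels: int, out_channels: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__(
            DepthwiseConv2d(in_channels, 3, stride=stride, padding=1, rng=rng),
            BatchNorm2d(in_channels),
            Conv2d(in_channels, out_channels, 1, rng=rng),
            BatchNorm2d(out_channels),
        )
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.stride = stride

    @property
    def depthwise(self) -> DepthwiseConv2d:
        return self.layers[0]

    @property
    def pointwise(self) -> Conv2d:
        return self.layers[2]


def _conv_unit(in_c: int, out_c: int, stride: int, use_dsc: bool,
               rng: np.random.Generator) -> Module:
    if use_dsc:
        return DSCConv(in_c, out_c, stride=stride, rng=rng)
    return Sequential(
        Conv2d(in_c, out_c, 3, stride=stride, padding=1, rng=rng),
        BatchNorm2d(out_c),
    )


class BasicBlock(Module):
    """Residual basic block: out = ReLU(branch(x) + shortcut(x))."""

    def __init__(self, in_channels: int, out_channels: int, stride: int,
                 use_dsc: bool, rng: np.random.Generator):
        super().__init__()
        self.branch = Sequential(
            _conv_unit(in_channels, out_channels, stride, use_dsc, rng),
            ReLU(),
            _conv_unit(out_channels, out_channels, 1, use_dsc, rng),
        )
        if stride != 1 or in_channels != out_channels:
            self.shortcut = Sequential(
                Conv2d(in_channels, out_channels, 1, stride=stride, rng=rng),
                BatchNorm2d(out_channels),
            )
        else:
            self.shortcut = None
        self.relu = ReLU()

    def forward(self, x):
        y = self.branch(x)
        s = self.shortcut(x) if self.shortcut is not None else x
        return self.relu(y + s)

    def backward(self, dout):
        d = self.relu.backward(dout)
        dx = self.branch.backward(d)
        if self.shortcut is not None:
            dx = dx + self.shortcut.backward(d)
        else:
            dx = dx + d
        return dx


class MSDCStem(Module):
    """Multi-scale dilated-convolution stem.

    Three parallel 3x3 convolutions (stride 2) with dilation rates d and
    padding d share the same input; their 64-channel outputs are fused either
    by concatenation (192 channels, reduced back to 64 by a 1x1 convolution)
    or by element-wise addition (no fusion convolution).
    """

    def __init__(self, in_channels: int, branch_channels: int, fused_channels: int,
                 dilations: tuple, fusion: str, rng: np.random.Generator):
        super().__init__()
        self.dilations = tuple(dilations)
        self.fusion = fusion
        self.branches = [
            Sequential(
                Conv2d(in_channels, branch_channels, 3, stride=2, padding=d,
                       dilation=d, rng=rng),
                BatchNorm2d(branch_channels),
            )
            for d in self.dilations
        ]
        if fusion == "concat":
            self.fuse = Sequential(
                Conv2d(branch_channels * len(self.dilations), fused_channels, 1, rng=rng),
                BatchNorm2d(fused_channels),
            )
        else:
            if branch_channels != fused_channels:
                raise ValueError("add fusion requires equal branch/fused channel counts")
            self.fuse = None
        self.relu = ReLU()
        self._n_branch_channels = branch_channels

    def forward(self, x):
        if x.shape[-2] < 7 or x.shape[-1] < 7:
            raise ValueError(
                f"stem input spatial dims {x.shape[-2:]} too small; the largest "
                "dilated kernel spans 7x7")
        ys = [b(x) for b in self.branches]
        if self.fusion == "concat":
            cat = np.concatenate(ys, axis=1)
            return self.relu(self.fuse(cat))
        return self.relu(self.fuse(sum(ys)) if self.fuse is not None else sum(ys))

    def backward(self, dout):
        d = self.relu.backward(dout)
        if self.fusion == "concat":
            dcat = self.fuse.backward(d)
            c = self._n_branch_channels
            parts = [dcat[:, i * c:(i + 1) * c] for i in range(len(self.branches))]
        else:
            parts = [d] * len(self.branches)
        dx = None
        for branch, dpart in zip(self.branches, parts):
            g = branch.backward(np.ascontiguousarray(dpart))
            dx = g if dx is None else dx + g
        return dx


class ChannelAttention(Module):
    """Squeeze channel descriptors (global avg & max pool), pass each through a
    shared bias-free bottleneck MLP (C -> C/r -> C), sum, sigmoid, and rescale
    the input channels."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        if channels % reduction != 0:
            raise ValueError(f"reduction {reduction} must divide channels {channels}")
        hidden = channels // reduction
        self.channels = channels
        self.w1 = Parameter(nn._he_normal(rng, (hidden, channels), channels))
        self.w2 = Parameter(nn._he_normal(rng, (channels, hidden), hidden))
        self._cache = None

    def _mlp(self, v):
        h = v @ self.w1.data.T
        hr = np.maximum(h, 0.0)
        return hr @ self.w2.data.T, v, hr

    def forward(self, x):
        n, c, h, w = x.shape
        avg = x.mean(axis=(2, 3))
        flat = x.reshape(n, c, h * w)
        mx_idx = flat.argmax(axis=2)
        mx = np.take_along_axis(flat, mx_idx[:, :, None], axis=2)[:, :, 0]
        s1, v1, h1 = self._mlp(avg)
        s2, v2, h2 = self._mlp(mx)
        attn = nn.sigmoid(s1 + s2)
        out = x * attn[:, :, None, None]
        self._cache = (x, attn, (v1, h1), (v2, h2), mx_idx)
        return out.astype(np.float32)

    def backward(self, dout):
        x, attn, p1, p2, mx_idx = self._cache
        n, c, h, w = x.shape
        dattn = (dout * x).sum(axis=(2, 3))
        dx = dout * attn[:, :, None, None]
        ds = dattn * attn * (1.0 - attn)
        dpooled = []
        for v, hr in (p1, p2):
            self.w2.grad += ds.T @ hr
            dh = (ds @ self.w2.data) * (hr > 0)
            self.w1.grad += dh.T @ v
            dpooled.append(dh @ self.w1.data)
        # avg-pool adjoint: spread uniformly
        dx = dx + dpooled[0][:, :, None, None] / (h * w)
        # max-pool adjoint: route to the arg-max location of each channel
        dflat = np.zeros((n, c, h * w), dtype=np.float32)
        np.put_along_axis(dflat, mx_idx[:, :, None], dpooled[1][:, :, None], axis=2)
        return (dx + dflat.reshape(n, c, h, w)).astype(np.float32)


class SpatialAttention(Module):
    """Channel-wise mean and max maps -> kxk conv (2->1, with bias) -> sigmoid
    -> broadcast spatial gate."""

    def __init__(self, kernel_size: int, rng: np.random.Generator):
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("spatial attention kernel must be odd")
        self.conv = Conv2d(2, 1, kernel_size, padding=(kernel_size - 1) // 2,
                           bias=True, rng=rng)
        self._cache = None

    def forward(self, x):
        n, c, h, w = x.shape
        avg_map = x.mean(axis=1, keepdims=True)
        mx_idx = x.argmax(axis=1)
        mx_map = np.take_along_axis(x, mx_idx[:, None], axis=1)
        cat = np.concatenate([avg_map, mx_map], axis=1)
        s = self.conv(cat)
        attn = nn.sigmoid(s)
        out = x * attn
        self._cache = (x, attn, mx_idx)
        return out.astype(np.float32)

    def backward(self, dout):
        x, attn, mx_idx = self._cache
        n, c, h, w = x.shape
        dattn = (dout * x).sum(axis=1, keepdims=True)
        dx = dout * attn
        ds = dattn * attn * (1.0 - attn)
        dcat = self.conv.backward(ds.astype(np.float32))
        dx = dx + dcat[:, 0:1] / c
        dmx = np.zeros_like(x)
        np.put_along_axis(dmx, mx_idx[:, None], dcat[:, 1:2], axis=1)
        return (dx + dmx).astype(np.float32)


class CBAM(Sequential):
    """Channel-then-spatial attention, applied sequentially."""

    def __init__(self, channels: int, reduction: int, spatial_kernel: int,
                 rng: np.random.Generator):
        super().__init__(
            ChannelAttention(channels, reduction, rng),
            SpatialAttention(spatial_kernel, rng),
        )


# ---------------------------------------------------------------------------
# full network
# ---------------------------------------------------------------------------


class LMCSleepNet(Module):
    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        super().__init__()
        config = config or ModelConfig()
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)

        if config.use_msdc:
            self.stem = MSDCStem(config.in_channels, config.stem_branch_channels,
                                 config.stem_fused_channels, config.dilations,
                                 config.msdc_fusion, rng)
        else:
            self.stem = Sequential(
                Conv2d(config.in_channels, config.stem_fused_channels, 7,
                       stride=2, padding=3, rng=rng),
                BatchNorm2d(config.stem_fused_channels),
                ReLU(),
            )
        self.maxpool = MaxPool2d(3, 2, 1)

        blocks = []
        in_c = config.stem_fused_channels
        for stage_idx, width in enumerate(config.stage_widths):
            for block_idx in range(config.blocks_per_stage):
                stride = 2 if (stage_idx > 0 and block_idx == 0) else 1
                blocks.append(BasicBlock(in_c, width, stride, config.use_dsc, rng))
                in_c = width
        self.stages = blocks

        if config.use_cbam:
            self.cbam = CBAM(config.stage_widths[-1], config.cbam_reduction,
                             config.spatial_kernel, rng)
        else:
            self.cbam = None
        self.gap = GlobalAvgPool2d()
        self.dropout = Dropout(config.dropout_p, rng=np.random.default_rng(
            rng.integers(0, 2**31)))
        self.fc = Linear(config.stage_widths[-1], config.num_classes, bias=True, rng=rng)

    # -- forward/backward ---------------------------------------------------
    def forward(self, x):
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite values in network input")
        x = self.stem(x)
        x = self.maxpool(x)
        for block in self.stages:
            x = block(x)
        if self.cbam is not None:
            x = self.cbam(x)
        x = self.gap(x)
        x = self.dropout(x)
        return self.fc(x)

    def backward(self, dlogits):
        d = self.fc.backward(dlogits)
        d = self.dropout.backward(d)
        d = self.gap.backward(d)
        if self.cbam is not None:
            d = self.cbam.backward(d)
        for block in reversed(self.stages):
            d = block.backward(d)
        d = self.maxpool.backward(d)
        return self.stem.backward(d)

    # -- inference ----------------------------------------------------------
    def features(self, x) -> np.ndarray:
        """[N,3,T,S] -> pooled [N, 512] feature vectors (no dropout/head)."""
        h = self.stem(x)
        h = self.maxpool(h)
        for block in self.stages:
            h = block(h)
        if self.cbam is not None:
            h = self.cbam(h)
        return self.gap(h)

    def classify(self, features: np.ndarray) -> Prediction:
        """Map one pooled feature vector through the FC head + softmax."""
        z = features @ self.fc.weight.data.T + self.fc.bias.data
        return Prediction(probabilities=softmax(z), logits=z)

    def predict_proba(self, x, batch_size: int = 64) -> np.ndarray:
        was_training = self.training
        self.eval()
        probs = []
        for i in range(0, len(x), batch_size):
            probs.append(softmax(self.forward(x[i:i + batch_size]), axis=1))
        if was_training:
            self.train()
        return np.concatenate(probs, axis=0)

    def predict(self, x, batch_size: int = 64) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)


def build_network(config: ModelConfig | None = None, seed: int = 0) -> LMCSleepNet:
    return LMCSleepNet(config, seed=seed)


# ---------------------------------------------------------------------------
# architecture description / parameter accounting
# ---------------------------------------------------------------------------


@dataclass
class LayerRecord:
    name: str
    kind: str
    kernel: int | None
    stride: int | None
    dilation: int | None
    in_channels: int | None
    out_channels: int | None
    param_shapes: list = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        return int(sum(int(np.prod(s)) for s in self.param_shapes))


@dataclass
class NetworkDescription:
    layers: list
    total_parameters: int


def describe(net: Module) -> NetworkDescription:
    """Enumerate every parameter-owning layer exactly once."""
    records = []
    for name, module in net.named_modules():
        own = [(k, v) for k, v in vars(module).items() if isinstance(v, Parameter)]
        if not own:
            continue
        records.append(LayerRecord(
            name=name,
            kind=type(module).__name__,
            kernel=getattr(module, "kernel_size", None),
            stride=getattr(module, "stride", None),
            dilation=getattr(module, "dilation", None),
            in_channels=getattr(module, "in_channels",
                                getattr(module, "channels", None)),
            out_channels=getattr(module, "out_channels",
                                 getattr(module, "channels", None)),
            param_shapes=[list(p.shape) for _, p in own],
        ))
    total = sum(r.n_parameters for r in records)
    return NetworkDescription(layers=records, total_parameters=total)


def count_parameters(net: Module | NetworkDescription) -> int:
    """Exact count of trainable scalars."""
    if isinstance(net, NetworkDescription):
        return net.total_parameters
    return sum(p.size for p in net.parameters())


def parameter_breakdown(net: LMCSleepNet) -> dict:
    """Parameter counts per architectural component (stem/body/cbam/head)."""
    groups = {"stem": 0, "body": 0, "cbam": 0, "head": 0}
    for name, p in net.named_parameters():
        if name.startswith("stem"):
            groups["stem"] += p.size
        elif name.startswith("stages"):
            groups["body"] += p.size
        elif name.startswith("cbam"):
            groups["cbam"] += p.size
        else:
            groups["head"] += p.size
    return groups
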