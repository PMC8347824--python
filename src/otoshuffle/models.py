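"""Residual classifiers for tympanic-membrane diagnosis.

Five variants are built here: plain 18- and 50-layer residual networks, both
with an optional Convolutional Block Attention Module (CBAM), and the
18-layer network with the shuffle attention module.  The shuffle module
builds a full 3-D (channel x height x width) multiplicative gate from three
cheap pieces: a space-to-depth rearrangement that folds each 2x2 spatial
block into four channels, a 1x1 convolution compressing the 4C intermediate
channels back to C, and a sigmoid followed by 2x nearest-neighbour
upsampling so the gate matches the input feature map elementwise.

Attention blocks are appended to the output of every residual block (8
blocks for the 18-layer net, 16 for the 50-layer net).  Parameter counts are
reported both exactly and truncated to millions (integer division), the
convention under which 13,963,844 prints as "13 M".
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor

BACKBONES = ("resnet18", "resnet50")
ATTENTIONS = ("none", "shuffle", "cbam")


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Architecture choice: backbone x attention x head width."""

    backbone: str = "resnet18"
    attention: str = "shuffle"
    num_classes: int = 4
    cbam_reduction: int = 16

    def __post_init__(self):
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}; choose from {BACKBONES}")
        if self.attention not in ATTENTIONS:
            raise ValueError(f"unknown attention {self.attention!r}; choose from {ATTENTIONS}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.cbam_reduction < 1:
            raise ValueError("cbam_reduction must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)


class ShuffleAttention(nn.Module):
    """3-D attention gate via space-to-depth channel shuffling.

    ``x -> x * upsample2x(sigmoid(conv1x1(space_to_depth(x))))`` where the
    1x1 convolution compresses 4C channels to C (bias-free), so the
    upsampled sigmoid map has exactly the input's shape and every gate value
    lies strictly in (0, 1).  Requires even spatial dimensions.
    """

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.channels = channels
        self.compress = nn.Conv2d(4 * channels, channels, kernel=1, bias=False, rng=rng)

    def attention_map(self, x: Tensor) -> Tensor:
        s = nn.space_to_depth(x)
        a = nn.sigmoid(self.compress(s))
        return nn.upsample_nearest2x(a)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        return nn.mul(x, self.attention_map(x))


class CBAM(nn.Module):
    """Convolutional Block Attention Module: sequential channel then
    spatial gating.

    The channel gate passes average- and max-pooled descriptors through a
    shared two-layer bottleneck (reduction ratio ``r``, bias-free) and sums
    them before the sigmoid; the spatial gate convolves the cross-channel
    mean and max maps with a 7x7 kernel.  With all weights zero both gates
    are exactly 0.5, so the block scales its input by 0.25.
    """

    def __init__(self, channels: int, reduction: int = 16, rng: np.random.Generator | None = None):
        super().__init__()
        if channels % reduction:
            raise ValueError(f"reduction {reduction} does not divide {channels} channels")
        self.channels = channels
        hidden = channels // reduction
        self.mlp_reduce = nn.Conv2d(channels, hidden, kernel=1, bias=False, rng=rng)
        self.mlp_expand = nn.Conv2d(hidden, channels, kernel=1, bias=False, rng=rng)
        self.spatial = nn.Conv2d(2, 1, kernel=7, padding=3, bias=True, rng=rng)

    def channel_gate(self, x: Tensor) -> Tensor:
        avg = self.mlp_expand(nn.relu(self.mlp_reduce(nn.spatial_mean(x))))
        mx = self.mlp_expand(nn.relu(self.mlp_reduce(nn.spatial_max(x))))
        return nn.sigmoid(nn.add(avg, mx))

    def spatial_gate(self, x: Tensor) -> Tensor:
        pooled = nn.concat_channels(nn.channel_mean(x), nn.channel_max(x))
        return nn.sigmoid(self.spatial(pooled))

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        x = nn.mul(x, self.channel_gate(x))
        return nn.mul(x, self.spatial_gate(x))


def _make_attention(kind: str, channels: int, reduction: int, rng) -> nn.Module:
    if kind == "none":
        return nn.Identity()
    if kind == "shuffle":
        return ShuffleAttention(channels, rng=rng)
    if kind == "cbam":
        return CBAM(channels, reduction=reduction, rng=rng)
    raise ValueError(f"unknown attention {kind!r}")


class BasicBlock(nn.Module):
    """Two 3x3 convolutions with identity (or 1x1-projected) skip."""

    expansion = 1

    def __init__(self, in_ch: int, out_ch: int, stride: int, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, padding=1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng)
            self.down_bn = nn.BatchNorm2d(out_ch)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x: Tensor) -> Tensor:
        out = nn.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        skip = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return nn.relu(nn.add(out, skip))


class Bottleneck(nn.Module):
    """1x1 reduce, 3x3, 1x1 expand (x4) with projected skip."""

    expansion = 4

    def __init__(self, in_ch: int, width: int, stride: int, rng):
        super().__init__()
        out_ch = width * self.expansion
        self.conv1 = nn.Conv2d(in_ch, width, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(width)
        self.conv2 = nn.Conv2d(width, width, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(width)
        self.conv3 = nn.Conv2d(width, out_ch, 1, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng)
            self.down_bn = nn.BatchNorm2d(out_ch)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x: Tensor) -> Tensor:
        out = nn.relu(self.bn1(self.conv1(x)))
        out = nn.relu(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        skip = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return nn.relu(nn.add(out, skip))


class AttendedBlock(nn.Module):
    """Residual block followed by its attention gate."""

    def __init__(self, block: nn.Module, attention: nn.Module):
        super().__init__()
        self.block = block
        self.attention = attention

    def forward(self, x: Tensor) -> Tensor:
        return self.attention(self.block(x))


_LAYER_PLANS = {
    "resnet18": (BasicBlock, (2, 2, 2, 2)),
    "resnet50": (Bottleneck, (3, 4, 6, 3)),
}


class ResNetClassifier(nn.Module):
    """Residual backbone + attention + global-average-pool linear head.

    The stem is the standard 7x7/2 convolution with 3x3/2 max-pooling; the
    four stages use base widths 64/128/256/512.  ``forward`` keeps a handle
    on the feature map entering the pooling head so Grad-CAM can read its
    activations and gradient after a backward pass.
    """

    def __init__(self, spec: ModelSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        block_cls, counts = _LAYER_PLANS[spec.backbone]
        self.conv1 = nn.Conv2d(3, 64, 7, stride=2, padding=3, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(64)
        self.maxpool = nn.MaxPool2d(3, 2, 1)
        stages: list[nn.Module] = []
        in_ch = 64
        for stage_idx, (width, n_blocks) in enumerate(zip((64, 128, 256, 512), counts)):
            blocks = []
            for b in range(n_blocks):
                stride = 2 if (stage_idx > 0 and b == 0) else 1
                block = block_cls(in_ch, width, stride, rng)
                in_ch = width * block_cls.expansion
                attn = _make_attention(spec.attention, in_ch, spec.cbam_reduction, rng)
                blocks.append(AttendedBlock(block, attn))
            stages.append(nn.Sequential(*blocks))
        self.stages = stages
        self.fc = nn.Linear(in_ch, spec.num_classes, rng=rng)
        self.feature_dim = in_ch
        self._last_feature_map: Tensor | None = None

    def features(self, x: Tensor) -> Tensor:
        out = nn.max_pool2d(nn.relu(self.bn1(self.conv1(x))), 3, 2, 1)
        for stage in self.stages:
            out = stage(out)
        return out

    def forward(self, x: Tensor) -> Tensor:
        fmap = self.features(x)
        self._last_feature_map = fmap
        return self.fc(nn.global_avg_pool(fmap))

    @property
    def last_feature_map(self) -> Tensor:
        """Activations of the last convolutional stage (post-attention),
        recorded by the most recent forward pass."""
        if self._last_feature_map is None:
            raise RuntimeError("run a forward pass before reading the feature map")
        return self._last_feature_map


def build_model(spec: ModelSpec, seed: int = 0) -> ResNetClassifier:
    """Instantiate one of the Table-style variants with seeded init."""
    return ResNetClassifier(spec, seed=seed)


def count_parameters(model: nn.Module) -> tuple[int, int]:
    """Exact trainable-parameter count and the truncated-millions figure."""
    exact = int(sum(p.size for p in model.parameters()))
    return exact, exact // 1_000_000


def shuffle_param_delta(channel_widths=(64, 64, 128, 128, 256, 256, 512, 512)) -> int:
    """Closed-form extra parameters of per-block shuffle gating: one
    bias-free 1x1 conv mapping 4C -> C per gated block, i.e. sum of 4C^2."""
    return int(sum(4 * c * c for c in channel_widths))


def save_checkpoint(model: ResNetClassifier, path: str | Path) -> None:
    """Write weights (.npz) plus a JSON sidecar with the spec and count."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    exact, millions = count_parameters(model)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "model_spec": model.spec.to_dict(),
        "parameters_exact": exact,
        "parameters_millions_truncated": millions,
    }, indent=2))


def load_checkpoint(path: str | Path) -> ResNetClassifier:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    model = build_model(ModelSpec.from_dict(sidecar["model_spec"]))
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        model.load_state_dict(dict(z))
    return model
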