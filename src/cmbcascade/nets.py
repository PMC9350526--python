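"""The two cascade architectures.

Stage 1 — a residual U-Net: a five-stage encoder built from residual blocks
(S1 keeps shape, S2 projects channels/stride), bilinear-interpolation
upsampling in the decoder, and per-stage skip fusion.  It consumes a whole
slice and emits a coarse per-pixel foreground probability.

Stage 2 — a full-resolution network (FRN): no downsampling anywhere, a
residual atrous spatial pyramid pooling (R-ASPP) block in the middle to mix
multi-scale context, operating on small ROI patches around stage-1 candidates.

Channel widths can be divided by an integer ``width_factor`` so the same
topology trains quickly at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autograd import Tensor, concatenate

__all__ = [
    "ResUNetSpec", "FrnSpec", "ResBlock", "ResUNet", "RAspp", "FRN",
    "PaddingRequiredError", "build_coarse_net", "build_fine_net",
]


class PaddingRequiredError(ValueError):
    """Raised when an input's spatial size is incompatible with the encoder."""


@dataclass(frozen=True)
class ResUNetSpec:
    """Configuration of the coarse residual U-Net.

    stage_channels are divided by width_factor (min 1 channel per stage).
    """

    input_channels: int = 1
    stage_channels: tuple = (32, 64, 128, 256, 512)
    width_factor: int = 1
    dtype: str = "float32"

    def channels(self) -> tuple:
        return tuple(max(1, c // self.width_factor) for c in self.stage_channels)

    def asdict(self) -> dict:
        return {"kind": "res_unet", "input_channels": self.input_channels,
                "stage_channels": list(self.stage_channels),
                "width_factor": self.width_factor}


@dataclass(frozen=True)
class FrnSpec:
    """Configuration of the fine full-resolution network."""

    input_channels: int = 1
    width: int = 32
    dilation_rates: tuple = (6, 8, 12)
    width_factor: int = 1
    dtype: str = "float32"

    def channels(self) -> int:
        return max(1, self.width // self.width_factor)

    def asdict(self) -> dict:
        return {"kind": "frn", "input_channels": self.input_channels,
                "width": self.width, "dilation_rates": list(self.dilation_rates),
                "width_factor": self.width_factor}


class ResBlock(nn.Module):
    """Residual unit: out = relu(h(x) + F(x)).

    F is conv3x3-BN-ReLU-conv3x3-BN.  Variant S1 uses an identity shortcut
    (channels and spatial size preserved); S2 adds a 1×1 projection
    convolution on the shortcut so channels and/or stride may change.
    """

    def __init__(self, cin, cout, variant="S1", stride=1, rng=None, dtype=np.float32):
        super().__init__()
        if variant == "S1" and (cin != cout or stride != 1):
            raise ValueError("S1 blocks preserve channel count and spatial size")
        self.variant = variant
        self.conv1 = nn.Conv2d(cin, cout, 3, stride=stride, padding=1, rng=rng, dtype=dtype)
        self.bn1 = nn.BatchNorm2d(cout, dtype=dtype)
        self.conv2 = nn.Conv2d(cout, cout, 3, padding=1, rng=rng, dtype=dtype)
        self.bn2 = nn.BatchNorm2d(cout, dtype=dtype)
        if variant == "S2":
            self.proj = nn.Conv2d(cin, cout, 1, stride=stride, rng=rng, dtype=dtype)
            self.bn_proj = nn.BatchNorm2d(cout, dtype=dtype)

    def forward(self, x):
        r = self.bn1(self.conv1(x)).relu()
        r = self.bn2(self.conv2(r))
        if self.variant == "S2":
            shortcut = self.bn_proj(self.proj(x))
        else:
            shortcut = x
        return (shortcut + r).relu()


def _conv_bn_relu(cin, cout, kernel, rng, dtype, padding=None):
    if padding is None:
        padding = kernel // 2
    return nn.Sequential(
        nn.Conv2d(cin, cout, kernel, padding=padding, rng=rng, dtype=dtype),
        nn.BatchNorm2d(cout, dtype=dtype),
        nn.ReLU(),
    )


class ResUNet(nn.Module):
    """Coarse-stage residual U-Net (encoder S1/S2 blocks, bilinear decoder).

    Stage 1: one conv-BN-ReLU to c0 channels, full resolution.
    Stage 2: 2×2 max-pool transition (with 1×1 channel doubling) + 3×S1.
    Stages 3, 4: 1×S2 (stride 2) + 3×S1.
    Stage 5: 2×S1 + 1×S2 (stride 2) to the c4-channel bottleneck.
    Decoder: ×2 bilinear upsampling, skip concatenation, two conv-BN-ReLU
    per stage, 1×1 output conv, logistic output.
    Input height and width must be divisible by 16.
    """

    def __init__(self, spec: ResUNetSpec = ResUNetSpec(), rng=None):
        super().__init__()
        self.spec = spec
        rng = rng or np.random.default_rng(0)
        dtype = np.dtype(spec.dtype).type
        c0, c1, c2, c3, c4 = spec.channels()

        self.stage1 = _conv_bn_relu(spec.input_channels, c0, 3, rng, dtype)
        self.pool = nn.MaxPool2d()
        self.transition2 = _conv_bn_relu(c0, c1, 1, rng, dtype)
        self.stage2 = nn.Sequential(*[ResBlock(c1, c1, "S1", rng=rng, dtype=dtype)
                                      for _ in range(3)])
        self.stage3 = nn.Sequential(
            ResBlock(c1, c2, "S2", stride=2, rng=rng, dtype=dtype),
            *[ResBlock(c2, c2, "S1", rng=rng, dtype=dtype) for _ in range(3)])
        self.stage4 = nn.Sequential(
            ResBlock(c2, c3, "S2", stride=2, rng=rng, dtype=dtype),
            *[ResBlock(c3, c3, "S1", rng=rng, dtype=dtype) for _ in range(3)])
        self.stage5 = nn.Sequential(
            ResBlock(c3, c3, "S1", rng=rng, dtype=dtype),
            ResBlock(c3, c3, "S1", rng=rng, dtype=dtype),
            ResBlock(c3, c4, "S2", stride=2, rng=rng, dtype=dtype))

        self.up = nn.UpsampleBilinear2x()
        self.dec4 = nn.Sequential(_conv_bn_relu(c4 + c3, c3, 3, rng, dtype),
                                  _conv_bn_relu(c3, c3, 3, rng, dtype))
        self.dec3 = nn.Sequential(_conv_bn_relu(c3 + c2, c2, 3, rng, dtype),
                                  _conv_bn_relu(c2, c2, 3, rng, dtype))
        self.dec2 = nn.Sequential(_conv_bn_relu(c2 + c1, c1, 3, rng, dtype),
                                  _conv_bn_relu(c1, c1, 3, rng, dtype))
        self.dec1 = nn.Sequential(_conv_bn_relu(c1 + c0, c0, 3, rng, dtype),
                                  _conv_bn_relu(c0, c0, 3, rng, dtype))
        self.out_conv = nn.Conv2d(c0, 1, 1, rng=rng, dtype=dtype)

    def forward(self, x):
        x = Tensor._wrap(x)
        h, w = x.data.shape[-2:]
        if h % 16 or w % 16:
            raise PaddingRequiredError(
                f"input {h}x{w} not divisible by 16; pad the image first")
        f1 = self.stage1(x)                                  # c0, H
        f2 = self.stage2(self.transition2(self.pool(f1)))    # c1, H/2
        f3 = self.stage3(f2)                                 # c2, H/4
        f4 = self.stage4(f3)                                 # c3, H/8
        f5 = self.stage5(f4)                                 # c4, H/16
        d4 = self.dec4(concatenate([self.up(f5), f4]))
        d3 = self.dec3(concatenate([self.up(d4), f3]))
        d2 = self.dec2(concatenate([self.up(d3), f2]))
        d1 = self.dec1(concatenate([self.up(d2), f1]))
        return self.out_conv(d1).sigmoid()


class RAspp(nn.Module):
    """Residual atrous spatial pyramid pooling.

    Three parallel 3×3 dilated convolutions (padding = dilation, so size is
    preserved) and a global-average-pooling branch are summed, fused by a 1×1
    convolution back to the input channel count, and added to the identity
    shortcut:  out = K1 * (sum_i Kd_i * f0 + AP(f0)) + f0.
    With all convolution kernels at zero the block is the identity map.
    """

    def __init__(self, channels, dilation_rates=(6, 8, 12), rng=None, dtype=np.float32):
        super().__init__()
        self.dilation_rates = tuple(dilation_rates)
        self.branches = [
            nn.Sequential(nn.Conv2d(channels, channels, 3, padding=d, dilation=d,
                                    rng=rng, dtype=dtype),
                          nn.BatchNorm2d(channels, dtype=dtype))
            for d in self.dilation_rates]
        self.gap = nn.GlobalAvgPool()
        self.fuse = nn.Conv2d(channels, channels, 1, rng=rng, dtype=dtype)
        self.bn_fuse = nn.BatchNorm2d(channels, dtype=dtype)

    def forward(self, f0):
        f0 = Tensor._wrap(f0)
        acc = self.branches[0](f0)
        for br in self.branches[1:]:
            acc = acc + br(f0)
        acc = acc + self.gap(f0)          # broadcast over space
        f_aspp = self.bn_fuse(self.fuse(acc))
        return f_aspp + f0


class FRN(nn.Module):
    """Fine-stage full-resolution network.

    conv-in (3×3 → width channels) → 3×S1 → R-ASPP → 3×S1 → conv-out
    (1×1 → 1 channel) → logistic.  No layer changes the spatial size, so the
    probability map is emitted at the ROI's native resolution.  The patch must
    be larger than the largest dilation rate.
    """

    def __init__(self, spec: FrnSpec = FrnSpec(), rng=None):
        super().__init__()
        self.spec = spec
        rng = rng or np.random.default_rng(0)
        dtype = np.dtype(spec.dtype).type
        w = spec.channels()
        self.conv_in = _conv_bn_relu(spec.input_channels, w, 3, rng, dtype)
        self.blocks_pre = nn.Sequential(*[ResBlock(w, w, "S1", rng=rng, dtype=dtype)
                                          for _ in range(3)])
        self.raspp = RAspp(w, spec.dilation_rates, rng=rng, dtype=dtype)
        self.blocks_post = nn.Sequential(*[ResBlock(w, w, "S1", rng=rng, dtype=dtype)
                                           for _ in range(3)])
        self.conv_out = nn.Conv2d(w, 1, 1, rng=rng, dtype=dtype)

    def forward(self, x):
        x = Tensor._wrap(x)
        h, w = x.data.shape[-2:]
        dmax = max(self.spec.dilation_rates)
        if min(h, w) <= dmax:
            raise ValueError(
                f"patch {h}x{w} too small for dilation rate {dmax}")
        f = self.conv_in(x)
        f = self.blocks_pre(f)
        f = self.raspp(f)
        f = self.blocks_post(f)
        return self.conv_out(f).sigmoid()


def build_coarse_net(width_factor: int = 1, seed: int = 0,
                     dtype: str = "float32") -> ResUNet:
    spec = ResUNetSpec(width_factor=width_factor, dtype=dtype)
    return ResUNet(spec, rng=np.random.default_rng(seed))


def build_fine_net(width_factor: int = 1, dilation_rates=(6, 8, 12), seed: int = 0,
                   dtype: str = "float32") -> FRN:
    spec = FrnSpec(dilation_rates=tuple(dilation_rates), width_factor=width_factor,
                   dtype=dtype)
    return FRN(spec, rng=np.random.default_rng(seed))
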