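"""CNN encoder pyramid, channel-prior convolutional blocks, and the
patch-expanding upsampler.

The encoder is a three-stage (configurable) convolutional pyramid: a
strided stem to the first scale, then per-stage stacks of channel-prior
convolutional attention (CPCA) blocks with strided downsampling
convolutions between stages. A CPCA block gates channels with a pooled
bottleneck MLP, refines space with multi-scale depthwise strip
convolutions (1xk and kx1 pairs), mixes pointwise, and adds the result
residually.

Patch expanding is the inverse of patch merging: a linear channel
expansion followed by pixel rearrangement, doubling each spatial
dimension and halving the channel count.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor, as_tensor
from .config import CasaConfig, ConfigError, StagePlan

__all__ = ["CpcaBlock", "PatchExpand", "Encoder", "cpca_block", "patch_expand"]

STRIP_KERNELS = (5, 7, 11, 21)


def _wrap(x):
    if isinstance(x, Tensor):
        return x, False
    return as_tensor(np.asarray(x, dtype=np.float64)), True


class CpcaBlock(nn.Module):
    """Channel-prior convolutional attention block (shape-preserving)."""

    def __init__(self, channels: int, reduction: int = 8):
        super().__init__()
        hidden = max(channels // reduction, 4)
        self.fc1 = nn.Conv2d(channels, hidden, 1)
        self.fc2 = nn.Conv2d(hidden, channels, 1)
        self.strips_a = nn.ModuleList([nn.DWConv2d(channels, (1, k)) for k in STRIP_KERNELS])
        self.strips_b = nn.ModuleList([nn.DWConv2d(channels, (k, 1)) for k in STRIP_KERNELS])
        self.mixer = nn.Conv2d(channels, channels, 1)
        self.norm = nn.LayerNorm2d(channels)

    def channel_gate(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(2, 3), keepdims=True)
        return ad.sigmoid(self.fc2(ad.relu(self.fc1(pooled))))

    def forward(self, x: Tensor) -> Tensor:
        y = self.norm(x)
        y = y * self.channel_gate(y)
        s = None
        for k, ca, cb in zip(STRIP_KERNELS, self.strips_a, self.strips_b):
            p = k // 2
            part = cb(_pad_hw(ca(_pad_hw(y, 0, p)), p, 0))
            s = part if s is None else s + part
        return x + self.mixer(s)


def _pad_hw(x: Tensor, ph: int, pw: int) -> Tensor:
    """Zero-pad H by ph and W by pw (asymmetric axes, symmetric sides)."""
    if ph == 0 and pw == 0:
        return x
    B, C, H, W = x.shape
    if pw:
        z = as_tensor(np.zeros((B, C, H, pw)))
        x = ad.concat([z, x, z], axis=3)
    if ph:
        B, C, H, W = x.shape
        z = as_tensor(np.zeros((B, C, ph, W)))
        x = ad.concat([z, x, z], axis=2)
    return x


class PatchExpand(nn.Module):
    """Upsampler halving channels and doubling spatial dims.

    Linear expansion C -> 2C on tokens, then each position's 2C channels
    are rearranged into a 2x2 block of C/2 channels.
    """

    def __init__(self, channels: int):
        super().__init__()
        if channels % 2:
            raise ConfigError(f"patch expand needs even channels, got {channels}")
        self.expand = nn.Linear(channels, 2 * channels, bias=False)
        self.norm = nn.LayerNorm(channels // 2)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        t, _ = nn.to_tokens(x)          # (B, H*W, C)
        t = self.expand(t)              # (B, H*W, 2C)
        c_out = C // 2
        # (B,H,W,2,2,c_out) -> (B,H,2,W,2,c_out) -> (B,2H,2W,c_out)
        t = t.reshape(B, H, W, 2, 2, c_out).transpose(0, 1, 3, 2, 4, 5)
        t = t.reshape(B, 2 * H * 2 * W, c_out)
        t = self.norm(t)
        return nn.to_grid(t, (2 * H, 2 * W))


class Encoder(nn.Module):
    """Strided stem + per-stage CPCA (or CASA) stacks with downsampling.

    Returns the per-stage feature maps, shallowest first, at the scales
    of the plan (default 1/4, 1/8, 1/16 of the input resolution).
    """

    def __init__(self, plan: StagePlan, in_channels: int = 1,
                 block: str = "cpca", cpca_reduction: int = 8,
                 casa_cfg: CasaConfig | None = None, casa_order: str = "channel_pre"):
        super().__init__()
        plan.validate()
        self.plan = plan
        s0 = plan.stem_stride
        c = plan.channels_per_stage
        self.stem = nn.Conv2d(in_channels, c[0], 2 * s0 - 1, stride=s0, padding=s0 - 1)
        self.stem_norm = nn.LayerNorm2d(c[0])
        self.stages = nn.ModuleList()
        self.downs = nn.ModuleList()
        from .attention import CasaBlock
        for i, (ch, depth) in enumerate(zip(c, plan.blocks_per_stage)):
            if block == "cpca":
                mods = [CpcaBlock(ch, cpca_reduction) for _ in range(depth)]
            elif block == "casa":
                mods = [CasaBlock(ch, casa_cfg or CasaConfig(), order=casa_order)
                        for _ in range(depth)]
            else:
                raise ConfigError(f"unknown encoder block {block!r}")
            self.stages.append(nn.Sequential(*mods))
            if i + 1 < len(c):
                self.downs.append(nn.Sequential(
                    nn.Conv2d(ch, c[i + 1], 3, stride=2, padding=1),
                    nn.LayerNorm2d(c[i + 1]),
                ))

    def forward(self, x: Tensor) -> list[Tensor]:
        B, C, H, W = x.shape
        div = self.plan.stem_stride * 2 ** (len(self.plan.channels_per_stage) - 1)
        if H % div or W % div:
            raise ValueError(f"input spatial dims must be divisible by {div}, got {H}x{W}")
        y = self.stem_norm(self.stem(x))
        feats = []
        for i, stage in enumerate(self.stages):
            y = stage(y)
            feats.append(y)
            if i < len(self.downs):
                y = self.downs[i](y)
        return feats


# -- functional wrappers ----------------------------------------------------

def cpca_block(x, reduction: int = 8, module: CpcaBlock | None = None):
    xt, was_np = _wrap(x)
    if not np.all(np.isfinite(xt.data)):
        raise ValueError("input contains non-finite entries")
    if module is None:
        module = CpcaBlock(xt.shape[1], reduction)
    y = module(xt)
    return y.data if was_np else y


def patch_expand(x, module: PatchExpand | None = None):
    xt, was_np = _wrap(x)
    if module is None:
        module = PatchExpand(xt.shape[1])
    y = module(xt)
    return y.data if was_np else y


def encoder_forward(x, plan: StagePlan, module: Encoder | None = None, **kwargs):
    xt, was_np = _wrap(x)
    if module is None:
        module = Encoder(plan, in_channels=xt.shape[1], **kwargs)
    feats = module(xt)
    return [f.data for f in feats] if was_np else feats
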