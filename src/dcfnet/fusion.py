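"""Skip-connection fusion: concatenation, attention refinement, compression.

The SSCF block fuses an encoder skip feature with the upsampled decoder
feature at the same scale in three stages:

1. channel concatenation (or element-wise addition, as an ablation);
2. dual-residual refinement — a spatial/channel synergistic attention
   (SCSA) branch and a lightweight FFN branch, each applied to the
   layer-normalized input and scaled by a small learnable gamma;
3. channel compression back to the skip width (depthwise 3x3 + pointwise
   1x1 by default; pure pointwise as an ablation).

The SCSA operator here follows the published two-stage design it is
named after — shareable multi-semantic spatial attention (per-group 1D
depthwise convolutions on H- and W-pooled profiles producing a sigmoid
spatial gate) followed by progressive channel self-attention on pooled
tokens producing a channel gate — and is isolated behind one class so a
drop-in replacement cannot ripple through the block.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor, as_tensor
from .config import ConfigError, FusionConfig

__all__ = [
    "concat_features",
    "channel_shuffle",
    "SMSA",
    "PCSA",
    "SCSA",
    "LiteFFN",
    "SscfBlock",
    "scsa_attention",
    "lite_ffn",
    "sscf_block",
]


def _wrap(x):
    if isinstance(x, Tensor):
        return x, False
    return as_tensor(np.asarray(x, dtype=np.float64)), True


def concat_features(x1, x2):
    """Concatenate two (B, C, H, W) maps along channels, x1 first."""
    a, was_np = _wrap(x1)
    b, _ = _wrap(x2)
    if a.shape[0] != b.shape[0] or a.shape[2:] != b.shape[2:]:
        raise ValueError(f"batch/spatial mismatch: {a.shape} vs {b.shape}")
    y = ad.concat([a, b], axis=1)
    return y.data if was_np else y


def channel_shuffle(x: Tensor, groups: int) -> Tensor:
    B, C, H, W = x.shape
    if C % groups:
        raise ConfigError(f"channels {C} not divisible by shuffle groups {groups}")
    return x.reshape(B, groups, C // groups, H, W).transpose(0, 2, 1, 3, 4).reshape(B, C, H, W)


class SMSA(nn.Module):
    """Shareable multi-semantic spatial attention.

    Pools the map along W (resp. H) to per-row (per-column) channel
    profiles, refines each channel group with a 1D depthwise convolution
    of its own kernel size, and gates the input with the outer product of
    the two sigmoid profiles.
    """

    def __init__(self, channels: int, cfg: FusionConfig):
        super().__init__()
        ks = cfg.smsa_kernel_sizes
        if channels % len(ks):
            raise ConfigError(f"channels {channels} not divisible into {len(ks)} SMSA groups")
        self.group_ch = channels // len(ks)
        self.convs_h = nn.ModuleList([nn.DWConv2d(self.group_ch, (k, 1), padding=0) for k in ks])
        self.convs_w = nn.ModuleList([nn.DWConv2d(self.group_ch, (k, 1), padding=0) for k in ks])
        self.kernel_sizes = tuple(ks)
        self.norm_h = nn.LayerNorm2d(channels)
        self.norm_w = nn.LayerNorm2d(channels)

    def _profile(self, prof: Tensor, convs) -> Tensor:
        # prof: (B, C, L, 1); per-group depthwise 1D conv with 'same' padding
        outs = []
        for g, conv in enumerate(convs):
            part = prof[:, g * self.group_ch:(g + 1) * self.group_ch]
            k = self.kernel_sizes[g]
            p = k // 2
            B, Cg, L, _ = part.shape
            padded = ad.concat(
                [as_tensor(np.zeros((B, Cg, p, 1))), part, as_tensor(np.zeros((B, Cg, p, 1)))],
                axis=2,
            )
            outs.append(conv(padded))
        return ad.concat(outs, axis=1)

    def forward(self, x: Tensor) -> Tensor:
        gate_h = ad.sigmoid(self.norm_h(self._profile(x.mean(axis=3, keepdims=True), self.convs_h)))
        prof_w = x.mean(axis=2, keepdims=True).transpose(0, 1, 3, 2)  # (B,C,W,1)
        gate_w = ad.sigmoid(self.norm_w(self._profile(prof_w, self.convs_w))).transpose(0, 1, 3, 2)
        return x * gate_h * gate_w

    def saturate_gates(self, logit: float = 30.0):
        """Force both sigmoid gates toward 1 (open-gate limit) by zeroing
        the profile convolutions and driving the norm biases high."""
        for conv in list(self.convs_h) + list(self.convs_w):
            conv.weight.data[:] = 0.0
            conv.bias.data[:] = 0.0
        for norm in (self.norm_h, self.norm_w):
            norm.ln.weight.data[:] = 0.0
            norm.ln.bias.data[:] = logit


class PCSA(nn.Module):
    """Progressive channel self-attention producing a channel gate.

    Spatially pools the map to a small token set, runs single-layer
    channel (transposed) self-attention over the pooled tokens, averages
    the result spatially, and gates the input channels with its sigmoid.
    """

    def __init__(self, channels: int, cfg: FusionConfig):
        super().__init__()
        if channels % cfg.pcsa_heads:
            raise ConfigError(f"channels {channels} not divisible by pcsa_heads {cfg.pcsa_heads}")
        self.heads = cfg.pcsa_heads
        self.pool_size = cfg.pcsa_pool_size
        self.qkv = nn.Linear(channels, 3 * channels)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        pooled = ad.adaptive_avg_pool2d(x, self.pool_size)
        t, _ = nn.to_tokens(pooled)  # (B, n, C)
        n = t.shape[1]
        h, ch = self.heads, C // self.heads
        qkv = self.qkv(t).reshape(B, n, 3, h, ch).transpose(2, 0, 3, 4, 1)  # (3,B,h,ch,n)
        q, k, v = qkv[0], qkv[1], qkv[2]
        A = ad.softmax(ad.matmul(q, k.transpose(0, 1, 3, 2)) / np.sqrt(n), axis=-1)
        out = ad.matmul(A, v)                      # (B,h,ch,n)
        gate = ad.sigmoid(out.mean(axis=3).reshape(B, C, 1, 1))
        return x * gate


class SCSA(nn.Module):
    """Two-stage spatial+channel synergistic attention with a channel
    shuffle between the stages."""

    def __init__(self, channels: int, cfg: FusionConfig):
        super().__init__()
        cfg.validate()
        self.smsa = SMSA(channels, cfg)
        self.pcsa = PCSA(channels, cfg)
        self.groups = cfg.group_count

    def forward(self, x: Tensor) -> Tensor:
        y = self.smsa(x)
        y = channel_shuffle(y, self.groups)
        return self.pcsa(y)


class LiteFFN(nn.Module):
    """Lightweight convolutional FFN: 1x1 -> depthwise 3x3 -> GELU -> 1x1."""

    def __init__(self, channels: int, expansion: int = 2):
        super().__init__()
        hidden = channels * expansion
        self.pw1 = nn.Conv2d(channels, hidden, 1)
        self.dw = nn.DWConv2d(hidden, 3, padding=1)
        self.pw2 = nn.Conv2d(hidden, channels, 1)

    def forward(self, x: Tensor) -> Tensor:
        return self.pw2(ad.gelu(self.dw(self.pw1(x))))


class SscfBlock(nn.Module):
    """Skip-fusion block: aggregate -> dual-residual refine -> compress.

    ``cfg.aggregation``, ``cfg.main_module`` and ``cfg.compression``
    select the ablation variants; the default is concatenation +
    dual-residual SCSA-Block + depthwise-then-pointwise compression.
    """

    def __init__(self, channels: int, cfg: FusionConfig):
        super().__init__()
        cfg.validate(channels)
        self.cfg = cfg
        self.channels = channels
        inner = 2 * channels if cfg.aggregation == "concat" else channels
        self.norm1 = nn.LayerNorm2d(inner)
        self.scsa = SCSA(inner, cfg)
        if cfg.main_module == "scsa_block":
            self.gamma1 = nn.Parameter(np.full(inner, cfg.gamma_init))
            self.norm2 = nn.LayerNorm2d(inner)
            self.liteffn = LiteFFN(inner, cfg.liteffn_expansion)
            self.gamma2 = nn.Parameter(np.full(inner, cfg.gamma_init))
        if cfg.compression == "dwconv":
            self.comp_dw = nn.DWConv2d(inner, 3, padding=1)
            self.comp_pw = nn.Conv2d(inner, channels, 1)
        elif cfg.compression == "linear":
            self.comp_pw = nn.Conv2d(inner, channels, 1)
        elif inner != channels:
            raise ConfigError("compression 'none' requires additive aggregation")

    def compress(self, x: Tensor) -> Tensor:
        if self.cfg.compression == "dwconv":
            return self.comp_pw(self.comp_dw(x))
        if self.cfg.compression == "linear":
            return self.comp_pw(x)
        return x

    def forward(self, x1: Tensor, x2: Tensor) -> Tensor:
        if x1.shape != x2.shape:
            raise ValueError(f"skip/decoder shape mismatch: {x1.shape} vs {x2.shape}")
        if self.cfg.aggregation == "concat":
            x = ad.concat([x1, x2], axis=1)
        else:
            x = x1 + x2
        if self.cfg.main_module == "scsa_block":
            g1 = self.gamma1.reshape(1, -1, 1, 1)
            x = x + g1 * self.scsa(self.norm1(x))
            g2 = self.gamma2.reshape(1, -1, 1, 1)
            x = x + g2 * self.liteffn(self.norm2(x))
        else:  # plain SCSA refinement, no residual scaling
            x = self.scsa(self.norm1(x))
        return self.compress(x)


# -- functional wrappers (array in, array out) ------------------------------

def scsa_attention(x, cfg: FusionConfig, module: SCSA | None = None):
    xt, was_np = _wrap(x)
    if module is None:
        module = SCSA(xt.shape[1], cfg)
    y = module(xt)
    return y.data if was_np else y


def lite_ffn(x, expansion: int = 2, module: LiteFFN | None = None):
    xt, was_np = _wrap(x)
    if not np.all(np.isfinite(xt.data)):
        raise ValueError("input contains non-finite entries")
    if module is None:
        module = LiteFFN(xt.shape[1], expansion)
    y = module(xt)
    return y.data if was_np else y


def sscf_block(x1, x2, cfg: FusionConfig, module: SscfBlock | None = None):
    a, was_np = _wrap(x1)
    b, _ = _wrap(x2)
    if module is None:
        module = SscfBlock(a.shape[1], cfg)
    y = module(a, b)
    return y.data if was_np else y
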