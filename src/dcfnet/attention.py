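"""Channel-adaptive sparse attention: the dual-attention decoder block.

The block cascades two channel-attention operators with Mix-FFN layers,
each behind a pre-norm residual:

* **XCA** (cross-covariance attention) — attention over the d x d
  cross-covariance of L2-normalized queries and keys, so channels (not
  spatial positions) attend to each other; a learnable per-head
  temperature tau rescales the normalized similarities.
* **TKSA** (top-k sparse attention) — transposed (channel x channel)
  attention whose similarity rows are sparsified to their k largest
  entries before the softmax. Four branches at k = C/2, 2C/3, 3C/4,
  4C/5 of the per-head width run in parallel and are fused with
  learnable scalar weights alpha_i.

The default cascade order is channel-first (XCA -> FFN -> TKSA -> FFN);
sparse-first, parallel, and single-operator variants are provided to
span the ablation design space.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor, as_tensor
from .config import CasaConfig, ConfigError

__all__ = [
    "round_half_up",
    "l2_normalize_channels",
    "xca_attention",
    "topk_mask",
    "tksa_attention",
    "mix_ffn",
    "XCA",
    "TKSA",
    "MixFFN",
    "CasaBlock",
]


def round_half_up(x: float) -> int:
    """round(f*C) with ties away from zero (no banker's rounding)."""
    return int(np.floor(x + 0.5))


def _wrap(x):
    """Accept ndarray or Tensor; report whether the caller used arrays."""
    if isinstance(x, Tensor):
        return x, False
    return as_tensor(np.asarray(x, dtype=np.float64)), True


def l2_normalize_channels(x: Tensor, eps: float = 1e-12) -> Tensor:
    """L2-normalize each channel (column) of an (..., N, d) token matrix."""
    n2 = (x * x).sum(axis=-2, keepdims=True)
    return x / ((n2 + eps) ** 0.5)


def xca_attention(Q, K, V, tau: float = 1.0):
    """Cross-covariance attention on token matrices of shape (..., N, d).

    Computes ``V @ softmax(K^T Q / tau)`` where the d x d similarity is the
    cross-covariance of L2-normalized Q and K columns, and the softmax
    normalizes over the key-channel axis so each output channel's mixture
    weights over input channels sum to one.
    """
    Qt, was_np = _wrap(Q)
    Kt, _ = _wrap(K)
    Vt, _ = _wrap(V)
    if Qt.shape != Kt.shape or Qt.shape != Vt.shape:
        raise ValueError(f"Q/K/V shape mismatch: {Qt.shape}, {Kt.shape}, {Vt.shape}")
    if not (np.isscalar(tau) or isinstance(tau, Tensor)):
        raise ConfigError("tau must be a scalar")
    if np.isscalar(tau) and tau <= 0:
        raise ConfigError(f"temperature must be positive, got {tau}")
    Qn = l2_normalize_channels(Qt)
    Kn = l2_normalize_channels(Kt)
    S = ad.matmul(Kn.transpose(*range(Kn.ndim - 2), Kn.ndim - 1, Kn.ndim - 2), Qn) / tau
    A = ad.softmax(S, axis=-2)  # key-channel axis: columns sum to 1
    out = ad.matmul(Vt, A)
    return out.data if was_np else out


def topk_mask(S, k: int):
    """Sparsify each row of ``S``: keep entries >= the k-th largest row
    value, replace the rest with -inf (they vanish after softmax).
    Ties at the threshold are all kept."""
    S = np.asarray(S, dtype=np.float64)
    n = S.shape[-1]
    if not (1 <= k <= n):
        raise ConfigError(f"k={k} outside [1, {n}]")
    kth = np.partition(S, n - k, axis=-1)[..., n - k : n - k + 1]
    return np.where(S >= kth, S, -np.inf)


def _transposed_attention(Xc: Tensor, tau, k: int | None):
    """Channel-channel attention on a (B, heads, d, N) channel-major tensor.

    ``S = (Q K^T) * tau`` is d x d per head; rows are optionally top-k
    sparsified, softmaxed, and applied to V. Projections live in the
    calling module; this helper is the bare operator.
    """
    S = ad.matmul(Xc, Xc.transpose(0, 1, 3, 2)) * tau
    if k is not None:
        mask = topk_mask(S.data, k)
        S = S + np.where(np.isfinite(mask), 0.0, -np.inf)
    A = ad.softmax(S, axis=-1)
    return ad.matmul(A, Xc)


def tksa_attention(X, cfg: CasaConfig, tau: float = 1.0, alphas=None):
    """Functional top-k sparse attention on tokens (B, N, C) or (N, C).

    Splits channels into ``cfg.num_heads`` heads, computes the transposed
    similarity ``S = Q K^T * tau`` (Q = K = V = X here: the projection-free
    operator), masks each row to its k_i largest entries for every
    configured fraction, softmax-normalizes, applies to V, and returns the
    alpha-weighted sum of the branches.
    """
    Xt, was_np = _wrap(X)
    squeeze = Xt.ndim == 2
    if squeeze:
        Xt = Xt.reshape(1, *Xt.shape)
    B, N, C = Xt.shape
    h = cfg.num_heads
    if C % h:
        raise ConfigError(f"channels {C} not divisible by num_heads {h}")
    ch = C // h
    ks = [round_half_up(float(f) * ch) for f in cfg.k_fractions]
    if any(k < 1 for k in ks):
        raise ConfigError(f"a k fraction rounds to 0 for head width {ch}")
    if alphas is None:
        alphas = [cfg.branch_weight_init] * len(ks)
    # (B, N, C) -> (B, h, ch, N): channel-major per head
    Xc = Xt.reshape(B, N, h, ch).transpose(0, 2, 3, 1)
    out = None
    for k, a in zip(ks, alphas):
        branch = _transposed_attention(Xc, tau, k) * a
        out = branch if out is None else out + branch
    y = out.transpose(0, 3, 1, 2).reshape(B, N, C)
    if squeeze:
        y = y.reshape(N, C)
    return y.data if was_np else y


class _PerHeadScalar(nn.Module):
    """One learnable log-parameterized positive scalar per head."""

    def __init__(self, heads: int, init: float = 1.0):
        super().__init__()
        if init <= 0:
            raise ConfigError("temperature must initialize positive")
        self.log_value = nn.Parameter(np.full((heads, 1, 1), np.log(init)))

    def value(self) -> Tensor:
        return self.log_value.exp()


class XCA(nn.Module):
    """Cross-covariance attention layer with qkv/output projections."""

    def __init__(self, channels: int, cfg: CasaConfig):
        super().__init__()
        if channels % cfg.num_heads:
            raise ConfigError(f"channels {channels} not divisible by heads {cfg.num_heads}")
        self.heads = cfg.num_heads
        self.qkv = nn.Linear(channels, 3 * channels)
        self.proj = nn.Linear(channels, channels)
        self.temperature = _PerHeadScalar(cfg.num_heads, cfg.temperature_init)

    def forward(self, x: Tensor) -> Tensor:  # tokens (B, N, C)
        B, N, C = x.shape
        h, ch = self.heads, C // self.heads
        qkv = self.qkv(x).reshape(B, N, 3, h, ch).transpose(2, 0, 3, 1, 4)  # (3,B,h,N,ch)
        q, k, v = qkv[0], qkv[1], qkv[2]
        qn = l2_normalize_channels(q)
        kn = l2_normalize_channels(k)
        S = ad.matmul(kn.transpose(0, 1, 3, 2), qn) / self.temperature.value()
        A = ad.softmax(S, axis=-2)
        out = ad.matmul(v, A)  # (B,h,N,ch)
        return self.proj(out.transpose(0, 2, 1, 3).reshape(B, N, C))


class TKSA(nn.Module):
    """Multi-branch top-k sparse attention layer with projections."""

    def __init__(self, channels: int, cfg: CasaConfig):
        super().__init__()
        if channels % cfg.num_heads:
            raise ConfigError(f"channels {channels} not divisible by heads {cfg.num_heads}")
        self.heads = cfg.num_heads
        ch = channels // cfg.num_heads
        self.ks = [round_half_up(float(f) * ch) for f in cfg.k_fractions]
        if any(k < 1 for k in self.ks):
            raise ConfigError(f"a k fraction rounds to 0 for head width {ch}")
        self.qkv = nn.Linear(channels, 3 * channels)
        self.proj = nn.Linear(channels, channels)
        self.temperature = _PerHeadScalar(cfg.num_heads, cfg.temperature_init)
        self.alphas = nn.Parameter(np.full(len(self.ks), float(cfg.branch_weight_init)))

    def forward(self, x: Tensor) -> Tensor:  # tokens (B, N, C)
        B, N, C = x.shape
        h, ch = self.heads, C // self.heads
        qkv = self.qkv(x).reshape(B, N, 3, h, ch).transpose(2, 0, 3, 4, 1)  # (3,B,h,ch,N)
        q, k, v = qkv[0], qkv[1], qkv[2]
        S = ad.matmul(q, k.transpose(0, 1, 3, 2)) * self.temperature.value()
        out = None
        for i, kk in enumerate(self.ks):
            mask = topk_mask(S.data, kk)
            A = ad.softmax(S + np.where(np.isfinite(mask), 0.0, -np.inf), axis=-1)
            branch = ad.matmul(A, v) * self.alphas[i]
            out = branch if out is None else out + branch
        y = out.transpose(0, 3, 1, 2).reshape(B, N, C)  # (B,h,ch,N)->(B,N,C)
        return self.proj(y)


class MixFFN(nn.Module):
    """Feed-forward block with a depthwise 3x3 convolution inside the
    hidden layer: FC2(GELU(LN(DWConv(FC1 x) + FC1 x)))."""

    def __init__(self, channels: int, cfg: CasaConfig):
        super().__init__()
        hidden = channels * cfg.ffn_expansion
        self.fc1 = nn.Linear(channels, hidden)
        self.dw = nn.DWConv2d(hidden, 3, padding=1)
        self.norm = nn.LayerNorm(hidden)
        self.fc2 = nn.Linear(hidden, channels)

    def forward(self, x: Tensor, spatial) -> Tensor:  # tokens (B, N, C)
        H, W = spatial
        B, N, C = x.shape
        if N != H * W:
            raise ValueError(f"token count {N} incompatible with grid {H}x{W}")
        h = self.fc1(x)
        g = nn.to_grid(h, (H, W))
        g = self.dw(g)
        h = nn.to_tokens(g)[0] + h
        return self.fc2(ad.gelu(self.norm(h)))


def mix_ffn(X, spatial, cfg: CasaConfig, module: MixFFN | None = None):
    """Functional Mix-FFN on a token matrix (N, C) or (B, N, C)."""
    Xt, was_np = _wrap(X)
    squeeze = Xt.ndim == 2
    if squeeze:
        Xt = Xt.reshape(1, *Xt.shape)
    if module is None:
        module = MixFFN(Xt.shape[-1], cfg)
    y = module(Xt, spatial)
    if squeeze:
        y = y.reshape(*y.shape[1:])
    return y.data if was_np else y


class CasaBlock(nn.Module):
    """Dual-attention decoder block on NCHW feature maps.

    Residual cascade (channel-first default):
    LN->XCA (+x), LN->FFN (+x), LN->TKSA (+x), LN->FFN (+x).
    ``order`` selects the ablation variants: ``sparse_pre`` swaps the two
    attention stages, ``parallel`` averages them (single FFN after),
    ``channel_only``/``sparse_only`` keep one operator (+ its FFN).
    """

    def __init__(self, channels: int, cfg: CasaConfig, order: str = "channel_pre"):
        super().__init__()
        if order not in ("channel_pre", "sparse_pre", "parallel", "channel_only", "sparse_only"):
            raise ConfigError(f"unknown CASA order {order!r}")
        self.order = order
        self.channels = cfg_channels = channels
        cfg.validate(cfg_channels)
        need_xca = order != "sparse_only"
        need_tksa = order != "channel_only"
        if need_xca:
            self.norm1 = nn.LayerNorm(channels)
            self.xca = XCA(channels, cfg)
        if need_tksa:
            self.norm3 = nn.LayerNorm(channels)
            self.tksa = TKSA(channels, cfg)
        self.norm2 = nn.LayerNorm(channels)
        self.ffn1 = MixFFN(channels, cfg)
        if order in ("channel_pre", "sparse_pre"):
            self.norm4 = nn.LayerNorm(channels)
            self.ffn2 = MixFFN(channels, cfg)

    def forward(self, x: Tensor) -> Tensor:  # (B, C, H, W)
        t, spatial = nn.to_tokens(x)
        o = self.order
        if o == "channel_pre":
            t = t + self.xca(self.norm1(t))
            t = t + self.ffn1(self.norm2(t), spatial)
            t = t + self.tksa(self.norm3(t))
            t = t + self.ffn2(self.norm4(t), spatial)
        elif o == "sparse_pre":
            t = t + self.tksa(self.norm3(t))
            t = t + self.ffn1(self.norm2(t), spatial)
            t = t + self.xca(self.norm1(t))
            t = t + self.ffn2(self.norm4(t), spatial)
        elif o == "parallel":
            t = t + (self.xca(self.norm1(t)) + self.tksa(self.norm3(t))) * 0.5
            t = t + self.ffn1(self.norm2(t), spatial)
        elif o == "channel_only":
            t = t + self.xca(self.norm1(t))
            t = t + self.ffn1(self.norm2(t), spatial)
        else:  # sparse_only
            t = t + self.tksa(self.norm3(t))
            t = t + self.ffn1(self.norm2(t), spatial)
        return nn.to_grid(t, spatial)


def casa_block(X_in, cfg: CasaConfig, order: str = "channel_pre",
               module: CasaBlock | None = None):
    """Functional wrapper: apply a (fresh or given) CASA block to a
    (B, C, H, W) feature map array or Tensor."""
    Xt, was_np = _wrap(X_in)
    if not np.all(np.isfinite(Xt.data)):
        raise ValueError("input feature map contains non-finite entries")
    if module is None:
        module = CasaBlock(Xt.shape[1], cfg, order=order)
    y = module(Xt)
    return y.data if was_np else y
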