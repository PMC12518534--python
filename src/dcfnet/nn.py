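"""Neural-network building blocks and optimizers over the autodiff core.

Layout conventions, fixed package-wide:

* feature maps are NCHW ``(batch, channels, height, width)``;
* token matrices are ``(batch, N, d)`` with ``N = H*W`` row-major
  (tokens enumerate rows of the grid first) and channels last.
"""

from __future__ import annotations

import math
from collections import OrderedDict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

_INIT_RNG = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Seed the global parameter-initialization RNG."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)
        self.requires_grad = True  # Parameters are trainable even under no_grad construction


class Module:
    """Base class: parameter registration, state dict, recursive walk."""

    def __init__(self):
        self._params: OrderedDict[str, Parameter] = OrderedDict()
        self._modules: OrderedDict[str, "Module"] = OrderedDict()

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", OrderedDict())[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", OrderedDict())[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield prefix + n, p
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_modules(self, prefix: str = ""):
        yield prefix.rstrip("."), self
        for n, m in self._modules.items():
            yield from m.named_modules(prefix + n + ".")

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {n: p.data.copy() for n, p in self.named_parameters()}

    def load_state_dict(self, sd: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(sd)
        extra = set(sd) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)}, unexpected={sorted(extra)}")
        for n, p in own.items():
            if p.data.shape != sd[n].shape:
                raise ValueError(f"shape mismatch for {n}: {p.data.shape} vs {sd[n].shape}")
            p.data = np.array(sd[n], dtype=np.float64)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        setattr(self, str(len(self._list)), m)
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = ModuleList(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _trunc_normal(shape, std=0.02):
    # resample-free clipped normal; adequate for init purposes
    return np.clip(_INIT_RNG.normal(0.0, std, size=shape), -2 * std, 2 * std)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features, self.out_features = in_features, out_features
        self.weight = Parameter(_trunc_normal((in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        y = ad.matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel_size, stride: int = 1,
                 padding: int = 0, groups: int = 1, bias: bool = True):
        super().__init__()
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        self.in_ch, self.out_ch = in_ch, out_ch
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = (in_ch // groups) * kh * kw
        bound = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(_INIT_RNG.normal(0.0, bound, size=(out_ch, in_ch // groups, kh, kw)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        ph, pw = (self.padding, self.padding) if isinstance(self.padding, int) else self.padding
        if ph != pw:
            raise ValueError("asymmetric padding unsupported")
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=ph, groups=self.groups)


class DWConv2d(Conv2d):
    """Depthwise convolution (groups == channels)."""

    def __init__(self, channels: int, kernel_size, padding: int = 0, bias: bool = True):
        super().__init__(channels, channels, kernel_size, stride=1,
                         padding=padding, groups=channels, bias=bias)


class LayerNorm(Module):
    """LN over the last (channel) axis of token tensors."""

    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.dim, self.eps = dim, eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def forward(self, x):
        return ad.layer_norm(x, self.weight, self.bias, eps=self.eps)


class LayerNorm2d(Module):
    """Channel LayerNorm for NCHW maps: normalizes over C at each pixel
    (the transformer convention applied to feature maps)."""

    def __init__(self, channels: int, eps: float = 1e-6):
        super().__init__()
        self.ln = LayerNorm(channels, eps=eps)

    def forward(self, x):
        y = x.transpose(0, 2, 3, 1)
        y = self.ln(y)
        return y.transpose(0, 3, 1, 2)


class GELU(Module):
    def forward(self, x):
        return ad.gelu(x)


# ---------------------------------------------------------------------------
# token <-> grid conversion (row-major, channels-last tokens)
# ---------------------------------------------------------------------------

def to_tokens(x: Tensor):
    """(B,C,H,W) -> ((B, H*W, C), (H, W))."""
    B, C, H, W = x.shape
    return x.transpose(0, 2, 3, 1).reshape(B, H * W, C), (H, W)

def to_grid(t: Tensor, spatial) -> Tensor:
    """(B, H*W, C) -> (B,C,H,W)."""
    H, W = spatial
    B, N, C = t.shape
    if N != H * W:
        raise ValueError(f"token count {N} != H*W = {H * W}")
    return t.reshape(B, H, W, C).transpose(0, 3, 1, 2)


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class SGD:
    """SGD with classical momentum and decoupled-from-nothing L2 weight decay
    (decay added to the gradient, the convention of common trainers)."""

    def __init__(self, params, lr: float, momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._buf = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._buf):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class Adam:
    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self):
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self._t
        bc2 = 1 - b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def poly_lr(base_lr: float, step: int, total_steps: int, power: float = 0.9) -> float:
    """Polynomial learning-rate decay, the standard schedule of 2D
    medical-segmentation training recipes."""
    frac = min(step, total_steps) / max(total_steps, 1)
    return base_lr * (1.0 - frac) ** power
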