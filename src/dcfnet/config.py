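"""Configuration records for the network, fusion blocks, and training.

Every architectural hyperparameter that the ablation tables span is a
field here, so each ablation row is just a different ``ModelConfig``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from fractions import Fraction

import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates a structural invariant."""


@dataclass
class CasaConfig:
    """Hyperparameters of the dual-attention decoder block.

    ``k_fractions`` are the sparsity levels of the top-k branches as
    fractions of the per-head channel count; the default four branches
    span k in [C/2, 4C/5]. One learnable temperature per head; one
    learnable fusion weight per branch (init 1).
    """

    num_heads: int = 4
    temperature_init: float = 1.0
    k_fractions: tuple = (Fraction(1, 2), Fraction(2, 3), Fraction(3, 4), Fraction(4, 5))
    branch_weight_init: float = 1.0
    ffn_expansion: int = 4

    def validate(self, channels: int | None = None):
        if self.num_heads < 1:
            raise ConfigError("num_heads must be positive")
        if self.temperature_init <= 0:
            raise ConfigError("temperature_init must be > 0")
        fr = [float(f) for f in self.k_fractions]
        if any(not (0 < f <= 1) for f in fr):
            raise ConfigError("k_fractions must lie in (0, 1]")
        if any(b >= a for a, b in zip(fr[1:], fr[:-1])):
            raise ConfigError("k_fractions must be strictly increasing")
        if self.ffn_expansion < 1:
            raise ConfigError("ffn_expansion must be positive")
        if channels is not None:
            if channels % self.num_heads:
                raise ConfigError(f"channels {channels} not divisible by num_heads {self.num_heads}")
            ch = channels // self.num_heads
            from .attention import round_half_up
            if any(round_half_up(float(f) * ch) < 1 for f in fr):
                raise ConfigError("a k_fraction rounds to k=0 for this head width")


@dataclass
class FusionConfig:
    """Hyperparameters of the skip-fusion (SSCF) block."""

    gamma_init: float = 1e-2
    smsa_kernel_sizes: tuple = (3, 5, 7, 9)
    pcsa_heads: int = 4
    group_count: int = 4
    pcsa_pool_size: int = 7
    liteffn_expansion: int = 2
    aggregation: str = "concat"        # concat | add        (Table-7 axis)
    main_module: str = "scsa_block"    # scsa_block | scsa   (dual-residual vs plain)
    compression: str = "dwconv"        # dwconv | linear | none

    def validate(self, channels: int | None = None):
        if not (0 < self.gamma_init <= 0.1):
            raise ConfigError("gamma_init must be in (0, 0.1]")
        if any(k % 2 == 0 for k in self.smsa_kernel_sizes):
            raise ConfigError("smsa_kernel_sizes must be odd")
        if self.aggregation not in ("concat", "add"):
            raise ConfigError(f"unknown aggregation {self.aggregation!r}")
        if self.main_module not in ("scsa_block", "scsa"):
            raise ConfigError(f"unknown main_module {self.main_module!r}")
        if self.compression not in ("dwconv", "linear", "none"):
            raise ConfigError(f"unknown compression {self.compression!r}")
        if channels is not None:
            inner = 2 * channels if self.aggregation == "concat" else channels
            if inner % self.group_count:
                raise ConfigError("channels not divisible by shuffle group_count")
            if inner % (2 * len(self.smsa_kernel_sizes)):
                raise ConfigError("channels not divisible by 2 * number of SMSA kernels")


@dataclass
class StagePlan:
    """Encoder pyramid plan: per-stage channels/depths and scales."""

    channels_per_stage: tuple = (160, 320, 640)
    blocks_per_stage: tuple = (3, 3, 3)
    scales: tuple = (Fraction(1, 4), Fraction(1, 8), Fraction(1, 16))

    def validate(self):
        n = len(self.channels_per_stage)
        if not (len(self.blocks_per_stage) == len(self.scales) == n):
            raise ConfigError("stage plan lists must have equal length")
        ch = self.channels_per_stage
        if any(b <= a for a, b in zip(ch, ch[1:])):
            raise ConfigError("channels must be strictly increasing across stages")
        sc = [Fraction(s).limit_denominator() for s in self.scales]
        for a, b in zip(sc[:-1], sc[1:]):
            if b * 2 != a:
                raise ConfigError("each stage scale must halve the previous one")
        for c_deep, c_shallow in zip(ch[:0:-1], ch[-2::-1]):
            if c_deep != 2 * c_shallow:
                raise ConfigError(
                    "stage channels must double per stage so patch expanding "
                    "(channel halving) aligns decoder and skip widths")

    @property
    def stem_stride(self) -> int:
        return int(1 / Fraction(self.scales[0]).limit_denominator())


@dataclass
class ModelConfig:
    """Full architectural record of the segmentation network."""

    stage_plan: StagePlan = field(default_factory=StagePlan)
    decoder_depths: tuple = (2, 2)
    bottleneck_depth: int = 2
    bottleneck_ffn_expansion: int = 6
    casa: CasaConfig = field(default_factory=CasaConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    num_classes: int = 9
    in_channels: int = 1
    img_size: int = 224
    casa_order: str = "channel_pre"   # channel_pre | sparse_pre | parallel | channel_only | sparse_only
    decoder_block: str = "casa"       # casa | conv       (ablation: no-CASA decoder)
    skip_fusion: str = "sscf"         # sscf | concat     (ablation: plain skip)
    encoder_block: str = "cpca"       # cpca | casa       (ablation: pure transformer encoder)
    cpca_reduction: int = 8

    def validate(self):
        self.stage_plan.validate()
        if len(self.decoder_depths) != len(self.stage_plan.channels_per_stage) - 1:
            raise ConfigError("decoder stage count must be encoder stage count - 1")
        if self.img_size % 16:
            raise ConfigError("img_size must be divisible by 16")
        if self.num_classes < 1:
            raise ConfigError("num_classes must be positive")
        if self.bottleneck_depth < 0:
            raise ConfigError("bottleneck_depth must be >= 0")
        if self.casa_order not in ("channel_pre", "sparse_pre", "parallel", "channel_only", "sparse_only"):
            raise ConfigError(f"unknown casa_order {self.casa_order!r}")
        if self.decoder_block not in ("casa", "conv"):
            raise ConfigError(f"unknown decoder_block {self.decoder_block!r}")
        if self.skip_fusion not in ("sscf", "concat"):
            raise ConfigError(f"unknown skip_fusion {self.skip_fusion!r}")
        if self.encoder_block not in ("cpca", "casa"):
            raise ConfigError(f"unknown encoder_block {self.encoder_block!r}")
        for c in self.stage_plan.channels_per_stage:
            self.casa.validate(c)
            self.fusion.validate(c)


@dataclass
class TrainConfig:
    """Optimization settings. The two built-in profiles mirror the two
    training recipes: SGD+momentum for CT/MRI multi-class tasks and Adam
    for the binary dermoscopy task."""

    optimizer: str = "sgd_momentum"   # sgd_momentum | adam
    lr: float = 3.4e-3
    momentum: float = 0.9
    weight_decay: float = 1e-4
    epochs: int = 400
    batch_size: int = 16
    lam: float = 0.4
    seed: int = 0
    lr_power: float = 0.9

    def validate(self):
        if self.optimizer not in ("sgd_momentum", "adam"):
            raise ConfigError(f"unknown optimizer {self.optimizer!r}")
        if self.lr <= 0:
            raise ConfigError("lr must be positive")
        if not (0 <= self.lam <= 1):
            raise ConfigError("lam must lie in [0, 1]")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be positive")


ISIC_TRAIN_PROFILE = TrainConfig(optimizer="adam", lr=1e-4, weight_decay=0.0,
                                 epochs=100, batch_size=4, lam=0.5)


# ---------------------------------------------------------------------------
# YAML (de)serialization — schema mirrors the dataclasses field-for-field
# ---------------------------------------------------------------------------

def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, Fraction):
        return str(obj)
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _maybe_fraction(v):
    if isinstance(v, str) and "/" in v:
        return Fraction(v)
    return v


def _from_plain(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.default_factory() if f.default_factory is not dataclasses.MISSING else None):
            v = _from_plain(type(f.default_factory()), v)
        elif isinstance(v, list):
            v = tuple(_maybe_fraction(x) for x in v)
        kwargs[f.name] = v
    return cls(**kwargs)


def model_config_to_yaml(cfg: ModelConfig) -> str:
    return yaml.safe_dump(_to_plain(cfg), sort_keys=False)


def model_config_from_yaml(text: str) -> ModelConfig:
    cfg = _from_plain(ModelConfig, yaml.safe_load(text) or {})
    cfg.validate()
    return cfg


def train_config_from_yaml(text: str) -> TrainConfig:
    cfg = _from_plain(TrainConfig, yaml.safe_load(text) or {})
    cfg.validate()
    return cfg
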