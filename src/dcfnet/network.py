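"""Full segmentation network: encoder, bottleneck, fused skips, dual-
attention decoder, projection head; parameter and FLOP accounting;
checkpoint save/load.

Forward path::

    encoder (3 scales) -> bottleneck (CASA blocks at 1/16)
      -> [patch expand -> skip fusion -> decoder blocks] x 2
      -> 1x1 projection at 1/4 scale -> 4x bilinear upsampling

yielding logits at the input resolution.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from . import autodiff as ad
from . import nn
from .attention import CasaBlock
from .autodiff import Tensor, as_tensor
from .backbone import CpcaBlock, Encoder, PatchExpand
from .config import ConfigError, ModelConfig, model_config_to_yaml, model_config_from_yaml
from .fusion import SscfBlock

__all__ = [
    "DCFNet",
    "build_model",
    "forward",
    "count_parameters",
    "count_flops",
    "count_casa_blocks",
    "save_checkpoint",
    "load_checkpoint",
]


class _ConvDecoderBlock(nn.Module):
    """Plain convolutional decoder block (no-attention ablation)."""

    def __init__(self, channels: int):
        super().__init__()
        self.conv1 = nn.Conv2d(channels, channels, 3, padding=1)
        self.norm1 = nn.LayerNorm2d(channels)
        self.conv2 = nn.Conv2d(channels, channels, 3, padding=1)
        self.norm2 = nn.LayerNorm2d(channels)

    def forward(self, x):
        y = ad.gelu(self.norm1(self.conv1(x)))
        return x + self.norm2(self.conv2(y))


class _PlainSkip(nn.Module):
    """Concatenation + pointwise compression (no-SSCF ablation)."""

    def __init__(self, channels: int):
        super().__init__()
        self.pw = nn.Conv2d(2 * channels, channels, 1)

    def forward(self, x1, x2):
        return self.pw(ad.concat([x1, x2], axis=1))


class DCFNet(nn.Module):
    """Dual-attention, cross-layer-fusion segmentation network."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        plan = cfg.stage_plan
        chans = plan.channels_per_stage
        self.encoder = Encoder(
            plan, in_channels=cfg.in_channels, block=cfg.encoder_block,
            cpca_reduction=cfg.cpca_reduction, casa_cfg=cfg.casa,
            casa_order=cfg.casa_order,
        )
        deep = chans[-1]
        bneck_casa = dataclasses.replace(
            cfg.casa, ffn_expansion=cfg.bottleneck_ffn_expansion)
        self.bottleneck = nn.Sequential(*[
            CasaBlock(deep, bneck_casa, order=cfg.casa_order)
            for _ in range(cfg.bottleneck_depth)
        ])
        self.expands = nn.ModuleList()
        self.skips = nn.ModuleList()
        self.dec_stages = nn.ModuleList()
        # decoder stages walk the pyramid upward: deepest skip first
        for i, depth in enumerate(cfg.decoder_depths):
            c_in = chans[len(chans) - 1 - i]
            c_out = c_in // 2
            self.expands.append(PatchExpand(c_in))
            if cfg.skip_fusion == "sscf":
                self.skips.append(SscfBlock(c_out, cfg.fusion))
            else:
                self.skips.append(_PlainSkip(c_out))
            if cfg.decoder_block == "casa":
                blocks = [CasaBlock(c_out, cfg.casa, order=cfg.casa_order)
                          for _ in range(depth)]
            else:
                blocks = [_ConvDecoderBlock(c_out) for _ in range(depth)]
            self.dec_stages.append(nn.Sequential(*blocks))
        self.head = nn.Conv2d(chans[0], cfg.num_classes, 1)
        self.head_scale = plan.stem_stride

    def forward(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = as_tensor(np.asarray(x, dtype=np.float64))
        B, C, H, W = x.shape
        if H != self.cfg.img_size or W != self.cfg.img_size:
            raise ValueError(
                f"input spatial size {H}x{W} != configured img_size {self.cfg.img_size}")
        feats = self.encoder(x)
        y = self.bottleneck(feats[-1])
        for i in range(len(self.dec_stages)):
            y = self.expands[i](y)
            skip = feats[len(feats) - 2 - i]
            y = self.skips[i](skip, y)
            y = self.dec_stages[i](y)
        logits = self.head(y)
        if self.head_scale > 1:
            logits = ad.upsample_bilinear(logits, self.head_scale)
        return logits


def build_model(cfg: ModelConfig, seed: int = 0) -> DCFNet:
    """Construct the network with seeded parameter initialization."""
    nn.manual_seed(seed)
    return DCFNet(cfg)


def forward(model: DCFNet, x) -> np.ndarray:
    """Inference forward pass returning logits as an ndarray."""
    with ad.no_grad():
        return model(as_tensor(np.asarray(x, dtype=np.float64))).data


def count_parameters(model: nn.Module) -> int:
    """Exact count of trainable scalars."""
    return int(sum(p.data.size for p in model.parameters()))


def count_flops(model: DCFNet, img_size: int | None = None,
                detailed: bool = False):
    """Multiply-accumulate count of a single-sample forward pass.

    Runs the model once at ``img_size`` under the primitive-level MAC
    counter and reports GFLOPs with one MAC counted as one FLOP
    (convolutions, linear layers and attention matrix products; element-
    wise ops and normalizations excluded).
    """
    size = img_size or model.cfg.img_size
    x = np.zeros((1, model.cfg.in_channels, size, size))
    old = model.cfg.img_size
    model.cfg.img_size = size
    try:
        with ad.no_grad(), ad.flop_counter() as rec:
            model(as_tensor(x))
    finally:
        model.cfg.img_size = old
    gflops = rec["macs"] / 1e9
    if detailed:
        return gflops, {k: v / 1e9 for k, v in rec["by_op"].items()}
    return gflops


def count_casa_blocks(model: nn.Module) -> int:
    """Structural walker counting dual-attention blocks in a model."""
    return sum(1 for _, m in model.named_modules() if isinstance(m, CasaBlock))


# ---------------------------------------------------------------------------
# checkpoints: single-file archive with the config embedded
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: DCFNet, extra: dict | None = None) -> None:
    payload = {f"param/{k}": v for k, v in model.state_dict().items()}
    payload["config_yaml"] = np.frombuffer(
        model_config_to_yaml(model.cfg).encode(), dtype=np.uint8)
    payload["extra_json"] = np.frombuffer(
        json.dumps(extra or {}).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_checkpoint(path, seed: int = 0):
    """Load (model, extra) from a checkpoint file."""
    with np.load(path) as z:
        cfg = model_config_from_yaml(bytes(z["config_yaml"]).decode())
        extra = json.loads(bytes(z["extra_json"]).decode())
        sd = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    model = build_model(cfg, seed=seed)
    model.load_state_dict(sd)
    return model, extra
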