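import numpy as np
import pytest

from dcfnet.config import CasaConfig, FusionConfig, ModelConfig, StagePlan


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_casa_cfg():
    """Dual-attention config sized for 8-channel unit-test blocks."""
    return CasaConfig(num_heads=2, ffn_expansion=2)


@pytest.fixture
def small_fusion_cfg():
    return FusionConfig()


def thin_model_config(**overrides) -> ModelConfig:
    """Width-reduced architecture for fast end-to-end tests."""
    defaults = dict(
        stage_plan=StagePlan(channels_per_stage=(8, 16, 32)),
        num_classes=2,
        img_size=32,
    )
    defaults.update(overrides)
    return ModelConfig(**defaults)


@pytest.fixture
def thin_cfg():
    return thin_model_config()
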