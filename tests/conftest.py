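import numpy as np
import pytest

from chromassay import EffectModel, RenderParams, default_effect_model


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture(scope="session")
def model() -> EffectModel:
    """Calibrated default generator (white mean ~45, black +20%)."""
    return default_effect_model()


@pytest.fixture(scope="session")
def small_render() -> RenderParams:
    """Small canvas for fast image tests; stage-5 disks still fit."""
    return RenderParams(canvas=(160, 192), roi_center=(80.0, 96.0), roi_semi_axes=(55.0, 70.0))
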