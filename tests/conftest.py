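import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_phantom():
    """A deterministic zero-noise phantom shared across tests."""
    from fxcallus.phantom import PhantomConfig, make_phantom

    cfg = PhantomConfig(group="F", day=14, shape=(4, 64, 64), noise_sd_hu=0.0, seed=7)
    vol, roi, truth = make_phantom(cfg)
    return cfg, vol, roi, truth


@pytest.fixture
def tiny_net_config():
    """Reduced-width network config used wherever full width is unnecessary."""
    from fxcallus.segnet import NetworkConfig

    return NetworkConfig(
        stage_dims=(4, 8), encoder_depths=(1, 1), patch_size=2,
        state_dim=2, ta_kernel=3, egm_atrous_rates=(1, 2), seed=0,
    )
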