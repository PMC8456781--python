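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
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """A small noiseless four-channel scene reused across tests."""
    from filotip import ChannelLaw, SceneConfig, make_scene

    cfg = SceneConfig(
        image_size=(192, 192),
        pixel_size=0.08,
        n_filopodia=6,
        filopodium_length_range=(2.0, 3.5),
        cell_radius=2.5,
        channel_models=(
            ChannelLaw("MYO10", "tip_exponential", 30000.0, decay_length=0.8),
            ChannelLaw("F-actin", "uniform", 20000.0),
            ChannelLaw("active-integrin", "tip_exponential", 25000.0,
                       decay_length=1.0, tip_positive_fraction=0.5),
            ChannelLaw("inactive-integrin", "shaft_uniform", 12000.0),
        ),
        poisson_scale=0.0,
        read_sd=0.0,
        seed=7,
    )
    return make_scene(cfg)
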