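import numpy as np
import pytest

from schoolsense.lightfield import FieldConfig, generate_field


@pytest.fixture(scope="session")
def small_field_config():
    """A short, coarse stimulus for fast integration tests (physical scales kept)."""
    return FieldConfig(
        grid_nx=94,
        grid_ny=54,
        border_px=5,
        noise_corr_px=1.0,
        frame_rate_hz=8.0,
        noise_persistence=0.9 ** (30.0 / 8.0),
        duration_s=40.0,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_field(small_field_config):
    return generate_field(small_field_config, keep_frames=True)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
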