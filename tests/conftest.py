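import numpy as np
import pytest

from agbmc import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_config():
    """Compact scene for unit tests: dense plots and wide LiDAR coverage so
    every pipeline stage has enough data at 80x80 pixels."""
    return SceneConfig(
        grid_rows=80, grid_cols=80, plot_spacing=500.0,
        lidar_coverage_fraction=0.5, lidar_strip_width=5,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_scene(small_config):
    return generate_scene(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
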