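import numpy as np
import pytest

from vegwater import GeneratorConfig, PipelineConfig, run_all
from vegwater.synthetic import generate_ndvi_cube, generate_scene


@pytest.fixture(scope="session")
def small_config():
    """A small scene: 16x16 pixels, 5 water years, default contamination."""
    return GeneratorConfig(seed=123, grid_size=16, n_years=5)


@pytest.fixture(scope="session")
def small_scene(small_config):
    return generate_scene(small_config)


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free, outlier-free, snow-free small scene (signal only)."""
    return GeneratorConfig(seed=7, grid_size=8, n_years=4, noise_sd=0.0,
                           annual_noise_sd=0.0, outlier_rate=0.0,
                           snow_max_composites=0)


@pytest.fixture(scope="session")
def clean_cube(clean_config):
    return generate_ndvi_cube(clean_config)


@pytest.fixture(scope="session")
def reference_result():
    """Full pipeline run on the reference scene (64x64, 19 water years)."""
    cfg = PipelineConfig(generator=GeneratorConfig(seed=1))
    return run_all(cfg)
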