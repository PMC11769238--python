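import numpy as np
import pytest

from vinevigor import GridGeoreference, Raster, SceneConfig, generate_scene


@pytest.fixture
def georef():
    return GridGeoreference(0.0, 100.0, 1.0)


@pytest.fixture
def fine_georef():
    return GridGeoreference(0.025, 49.975, 0.05)


@pytest.fixture(scope="session")
def small_scene():
    """Default-parameter scene at desk scale, shared across read-only tests."""
    return generate_scene(SceneConfig(extent=(20.0, 16.0), seed=1))


@pytest.fixture(scope="session")
def noiseless_scene():
    """Separable scene: no pixel noise, no per-vine spectral jitter."""
    cfg = SceneConfig(
        extent=(20.0, 16.0),
        seed=1,
        reflectance_noise_sd=0.0,
        leaf_reflectance_jitter_sd=(0.0,) * 5,
    )
    return generate_scene(cfg)


def make_raster(values, georef=None, nodata=-9999.0):
    return Raster(np.asarray(values, dtype=float), georef or GridGeoreference(0.0, 100.0, 1.0), nodata)
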