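import numpy as np
import pytest

from ricesits import autodiff as ad
from ricesits.synthetic import SceneConfig, build_dataset


@pytest.fixture
def float64_autodiff():
    """Run the engine in float64 for tight numerical tolerances."""
    prev = ad.DTYPE
    ad.DTYPE = np.float64
    yield
    ad.DTYPE = prev


@pytest.fixture(scope="session")
def tiny_scene():
    """Small five-class scene shared by read-only tests."""
    cfg = SceneConfig(n_polygons_per_class=6, points_per_polygon=2,
                      patch_size=1, gap_rate=0.3, seed=7)
    return build_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
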