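import numpy as np
import pytest

from firecarb.lidar import PointCloudTile
from firecarb.scene import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A compact but complete fire scene shared by the slower tests."""
    cfg = SceneConfig(grid_rows=28, grid_cols=28, buffer_width=7, seed=42)
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def small_metric_stack(small_scene):
    from firecarb.lidar import normalize_intensity, rasterize_metrics

    ref = small_scene.reference_range_m
    return rasterize_metrics(
        (normalize_intensity(t, ref) for t in small_scene.iter_tiles("post")),
        small_scene.shape)


def random_tile(rng, n_min=5, n_max=400, with_range=True):
    """A random but valid height-normalized tile."""
    n = int(rng.integers(n_min, n_max))
    heights = rng.uniform(-0.4, 40.0, size=n)
    intensity = rng.uniform(0.0, 120.0, size=n)
    rng_m = rng.uniform(400.0, 2500.0, size=n) if with_range else None
    return PointCloudTile(height_m=heights, intensity=intensity, range_m=rng_m,
                          cell_id=(0, 0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
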