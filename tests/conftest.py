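import numpy as np
import pytest

from soycloud import PointCloud, generate_scene


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_cloud(rng):
    """200 random points with color and both label arrays."""
    n = 200
    return PointCloud(
        coords=rng.uniform(-1, 1, (n, 3)),
        color=rng.integers(0, 256, (n, 3)),
        class_label=rng.integers(0, 2, n),
        instance_label=rng.integers(-1, 5, n),
    )


@pytest.fixture(scope="session")
def tiny_scene():
    """A small simple-category scene: fast enough for unit tests while
    keeping the full ground/plant/outlier structure."""
    return generate_scene(
        n_rows=1,
        plants_per_row=3,
        adhesion="simple",
        points_per_plant=(3000, 4000),
        ground_density=20000,
        rng_seed=11,
    )
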