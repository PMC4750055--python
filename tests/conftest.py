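import numpy as np
import pytest

from pestvision.fixtures import make_classification_dataset, make_localization_suite


@pytest.fixture(scope="session")
def easy_scenes():
    """Small easy suite shared by localization tests."""
    return make_localization_suite(10, seed=21, difficulty="easy", height=128, width=128)


@pytest.fixture(scope="session")
def one_scene(easy_scenes):
    return easy_scenes[0]


@pytest.fixture(scope="session")
def shape_dataset():
    return make_classification_dataset(3, 10, image_size=64, seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def random_region_instance(seed: int, max_side: int = 64, max_regions: int = 12):
    """A random small (image, RegionMap) pair for oracle comparisons.

    Regions are Voronoi cells of random sites, so labels are consecutive
    and every region is non-empty.
    """
    from pestvision.segmentation import RegionMap

    rng = np.random.default_rng(seed)
    h = int(rng.integers(16, max_side + 1))
    w = int(rng.integers(16, max_side + 1))
    n_regions = int(rng.integers(2, max_regions + 1))
    sites = rng.uniform(0, 1, (n_regions, 2)) * [h, w]
    ys, xs = np.mgrid[0:h, 0:w]
    d2 = (ys[..., None] - sites[:, 0]) ** 2 + (xs[..., None] - sites[:, 1]) ** 2
    labels = d2.argmin(axis=-1)
    _, labels = np.unique(labels, return_inverse=True)
    labels = labels.reshape(h, w).astype(np.int32)
    image = rng.integers(0, 256, (h, w, 3), dtype=np.uint8)
    return image, RegionMap(labels=labels, n_regions=int(labels.max()) + 1)
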