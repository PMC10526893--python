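import numpy as np
import pytest

from nodalmap.grid import ImageGrid
from nodalmap.phantom import PhantomSpec, build_template
from nodalmap.volume_io import BinaryMask, LevelLabelVolume


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec(seed=11)


@pytest.fixture(scope="session")
def template(default_spec):
    """Default phantom template (levels, body) — built once per session."""
    return build_template(default_spec)


@pytest.fixture
def small_grid() -> ImageGrid:
    return ImageGrid(shape=(16, 16, 12), spacing=(1.0, 1.0, 3.0))


def make_sphere_mask(grid: ImageGrid, center_mm, radius_mm) -> np.ndarray:
    """Boolean digital sphere: voxel centers within radius of a world point."""
    centers = grid.all_voxel_centers()
    d = np.linalg.norm(centers - np.asarray(center_mm), axis=-1)
    return d <= radius_mm


def make_label_volume(grid: ImageGrid, regions: dict[int, np.ndarray]) -> LevelLabelVolume:
    labels = np.zeros(grid.shape, dtype=np.int16)
    for code, mask in regions.items():
        labels[mask] = code
    return LevelLabelVolume(grid=grid, labels=labels)


def make_mask(grid: ImageGrid, values) -> BinaryMask:
    return BinaryMask(grid=grid, values=np.asarray(values, dtype=np.uint8))
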