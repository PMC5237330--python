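import numpy as np
import pytest

from shapeatlas import (
    BinaryVolume,
    PopulationSpec,
    VolumeGrid,
    make_base_shape,
    make_population,
)


def ball_volume(grid: VolumeGrid, radius_mm: float, center=None) -> BinaryVolume:
    """Digital ball: voxel centers within radius_mm of the (grid) center."""
    pos = grid.index_grid_physical()
    c = grid.center if center is None else np.asarray(center, dtype=float)
    occ = (np.linalg.norm(pos - c, axis=-1) <= radius_mm).astype(np.uint8)
    return BinaryVolume(grid, occ)


def random_binary(grid: VolumeGrid, rng, p=0.3, ensure_nonempty=True) -> BinaryVolume:
    occ = (rng.random(grid.dims) < p).astype(np.uint8)
    if ensure_nonempty and not occ.any():
        occ[tuple(d // 2 for d in grid.dims)] = 1
    return BinaryVolume(grid, occ)


@pytest.fixture
def unit_grid():
    return VolumeGrid((16, 16, 16), (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def small_population():
    """Four moderately warped blobs on a 32^3 grid (1.5 mm spacing)."""
    spec = PopulationSpec(
        n_cases=4,
        grid=VolumeGrid((32, 32, 32), (1.5, 1.5, 1.5)),
        base_radius=9.0,
        lobe_count=2,
        pose_sd=(0.05, 1.0),
        scale_sd=0.05,
        warp_amp=1.0,
        warp_smoothness=6.0,
        seed=1,
    )
    return make_population(spec)


@pytest.fixture(scope="session")
def lobed_shape():
    """Well-conditioned asymmetric blob for transform-recovery tests."""
    spec = PopulationSpec(
        n_cases=1,
        grid=VolumeGrid((40, 40, 40), (1.0, 1.0, 1.0)),
        base_radius=11.0,
        lobe_count=4,
        pose_sd=(0.0, 0.0),
        seed=3,
    )
    return make_base_shape(spec)
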