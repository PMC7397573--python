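import numpy as np
import pytest

from kbplan.features import LibraryMatrix
from kbplan.synthetic import GeometryParams, generate_library, generate_patient
from kbplan.volumes import StructureMask, VoxelGrid


@pytest.fixture
def small_grid() -> VoxelGrid:
    return VoxelGrid((24, 24, 16), (2.0, 2.0, 3.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_mask(grid: VoxelGrid, voxels, name: str = "m") -> StructureMask:
    return StructureMask(name, grid, voxels)


def digital_sphere(grid: VoxelGrid, center_mm, radius_mm) -> np.ndarray:
    xs, ys, zs = grid.coordinates_mm()
    cx, cy, cz = center_mm
    return (xs - cx) ** 2 + (ys - cy) ** 2 + (zs - cz) ** 2 <= radius_mm**2


#: coarse grid with the same physical extent as the default geometry;
#: keeps unit-test phantoms cheap
COARSE_PARAMS = GeometryParams(shape=(48, 48, 32), spacing_mm=(4.0, 4.0, 6.0))


@pytest.fixture(scope="session")
def phantom():
    return generate_patient(GeometryParams(seed=11))


@pytest.fixture(scope="session")
def coarse_phantom():
    from dataclasses import replace

    return generate_patient(replace(COARSE_PARAMS, seed=11))


@pytest.fixture(scope="session")
def small_library() -> LibraryMatrix:
    """A 12-patient coarse-grid library with a noiseless linear truth."""
    lib, _ = generate_library(12, seed=5, params=COARSE_PARAMS)
    return lib


@pytest.fixture(scope="session")
def knowledge_library() -> LibraryMatrix:
    """The 115-patient default-geometry noiseless library (slow; shared)."""
    lib, _ = generate_library(115, seed=1)
    return lib
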