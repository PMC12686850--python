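import numpy as np
import pytest

from glomquant.io import VoxelSpacing
from glomquant.synthetic import SyntheticSpec, generate_bulb

#: the anisotropic spacing of the study's annotated stacks
PAPER_SPACING = VoxelSpacing(1.76, 1.76, 5.0)
ISO_SPACING = VoxelSpacing(1.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def paper_spacing() -> VoxelSpacing:
    return PAPER_SPACING


@pytest.fixture(scope="session")
def iso_spacing() -> VoxelSpacing:
    return ISO_SPACING


@pytest.fixture(scope="session")
def small_bulb():
    """A 40-object ellipsoid bulb shared across tests (seeded)."""
    spec = SyntheticSpec(n_objects=40, volume_shape=(100, 400, 400), seed=123)
    vol, truth = generate_bulb(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def small_bulb_measurements(small_bulb):
    from glomquant.morphometry import measure_all

    spec, vol, truth = small_bulb
    table = measure_all(vol)
    return spec, vol, truth, table


def digitize_shape(family, semi_axes, spacing, rotation=None, exponent=1.0):
    """Voxelize one shape centered in a grid just large enough for it."""
    from scipy.spatial.transform import Rotation

    from glomquant.synthetic import voxelize_shape

    if rotation is None:
        rotation = Rotation.identity()
    bound = semi_axes[0] + 3 * max(spacing.dx, spacing.dy, spacing.dz)
    center = np.array([bound, bound, bound])
    grid_shape = (
        int(np.ceil(2 * bound / spacing.dz)) + 2,
        int(np.ceil(2 * bound / spacing.dy)) + 2,
        int(np.ceil(2 * bound / spacing.dx)) + 2,
    )
    mask, box = voxelize_shape(family, center, semi_axes, rotation, spacing,
                               grid_shape, exponent=exponent)
    full = np.zeros(grid_shape, dtype=bool)
    full[box] = mask
    return full


def mask_points(mask, spacing):
    """Voxel-center physical coordinates (x, y, z) of a mask."""
    zz, yy, xx = np.nonzero(mask)
    return np.column_stack([
        (xx + 0.5) * spacing.dx,
        (yy + 0.5) * spacing.dy,
        (zz + 0.5) * spacing.dz,
    ])
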