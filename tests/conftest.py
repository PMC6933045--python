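import math

import numpy as np
import pytest

from petharm.image import VolumetricImage


@pytest.fixture
def unit_grid():
    """Empty 21^3 image on a 1 mm isotropic grid centered at the origin."""
    n = 21
    return VolumetricImage(
        values=np.zeros((n, n, n)),
        spacing=(1.0, 1.0, 1.0),
        origin=(-(n - 1) / 2.0,) * 3,
        unit="SUV",
    )


@pytest.fixture
def coarse_grid():
    """Empty 20^3 image on a 4 mm grid (clinical-like voxel size)."""
    n = 20
    return VolumetricImage(
        values=np.zeros((n, n, n)),
        spacing=(4.0, 4.0, 4.0),
        origin=(-(n - 1) / 2.0 * 4.0,) * 3,
        unit="SUV",
    )


def sphere_image(grid, center, diameter, inside, outside=0.0):
    """Binary-rendered sphere on a grid (voxel-center membership)."""
    org = np.asarray(grid.origin)
    sp = np.asarray(grid.spacing)
    idx = np.indices(grid.shape)
    coords = org[:, None, None, None] + idx * sp[:, None, None, None]
    d2 = sum((coords[a] - center[a]) ** 2 for a in range(3))
    values = np.where(d2 <= (diameter / 2.0) ** 2, inside, outside)
    return grid.with_values(values)
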