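import numpy as np
import pytest

from readcov import synthdata
from readcov.volumes import GMVMap, ROISpec


@pytest.fixture
def small_cfg():
    """A fast two-group cohort config for unit tests."""
    return synthdata.SimulationConfig(
        n_per_group={"typical_child": 24, "poor_child": 18},
        rng_seed=123,
    )


@pytest.fixture
def map_cfg():
    """Config with a small voxel grid, seed sphere and one planted cluster."""
    grid = synthdata.MapGrid((16, 16, 16), 2.0)
    return synthdata.SimulationConfig(
        n_per_group={"typical_child": 20, "poor_child": 20},
        map_grid=grid,
        seed_roi=ROISpec("seed", (-8.0, -8.0, 0.0), 4.0),
        cluster_rois=[ROISpec("planted", (8.0, 8.0, 4.0), 4.0)],
        coupling_strength=0.08,
        noise_sd=0.05,
        rng_seed=42,
    )


@pytest.fixture
def unit_grid():
    """An empty 1 mm isotropic grid centred on the world origin."""
    shape = (21, 21, 21)
    affine = np.eye(4)
    affine[:3, 3] = -10.0
    return GMVMap(np.zeros(shape), affine)
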