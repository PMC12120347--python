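import datetime as dt

import numpy as np
import pytest

import pathvol as pv
from pathvol.pipeline import run_pipeline


@pytest.fixture(scope="session")
def flat_lake() -> pv.Bathymetry:
    """100 x 100 m lake of uniform 10 m depth on a 10 m grid."""
    return pv.Bathymetry(origin_x=0.0, origin_y=0.0, cell_size=10.0,
                         depth=np.full((10, 10), 10.0))


@pytest.fixture(scope="session")
def flat_grid(flat_lake) -> pv.VoxelGrid:
    return pv.build_voxel_grid(flat_lake, voxel_length=20.0, rescale=100.0)


@pytest.fixture(scope="session")
def small_lake() -> pv.Bathymetry:
    """Small paraboloid lake used for oracle-scale tests."""
    return pv.make_lake(pv.LakeSpec(radius=150.0, max_depth=20.0,
                                    cell_size=10.0))


@pytest.fixture(scope="session")
def scenario():
    """Desk-scale synthetic study: 4 OU benthivores over 8 days."""
    return pv.default_scenario(seed=7, n_fish=4, days=8)


@pytest.fixture(scope="session")
def pipeline_result(scenario):
    """Full pipeline run (with the v_swim sensitivity grid) on the scenario."""
    return run_pipeline(pv.Config(), scenario.positions, scenario.lake,
                        scenario.temperature, seed=7)


def make_position(fish="f1", t=0.0, x=0.0, y=0.0, depth=5.0, hpe=1.0):
    return pv.Position(fish_id=fish, t=t, x=x, y=y, depth=depth, hpe=hpe)


@pytest.fixture
def position_factory():
    return make_position
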