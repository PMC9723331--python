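"""Shared fixtures: phantom cohorts at the grid scales used across the suite."""

import numpy as np
import pytest

from cardioseg.mas import Atlas, AtlasLibrary
from cardioseg.phantom import PhantomParams, make_cohort, make_phantom


@pytest.fixture(scope="session")
def default_params():
    """Full desk-scale grid: 64³ voxels at 2.5 mm (160 mm field of view)."""
    return PhantomParams()


@pytest.fixture(scope="session")
def coarse_params():
    """Coarse grid for fast tests: 32³ voxels at 5 mm."""
    return PhantomParams(shape=(32, 32, 32), spacing=(5.0, 5.0, 5.0))


@pytest.fixture(scope="session")
def mid_params():
    """Intermediate grid: 40³ voxels at 4 mm."""
    return PhantomParams(shape=(40, 40, 40), spacing=(4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def phantom_case(default_params):
    return make_phantom(default_params, 42)


@pytest.fixture(scope="session")
def coarse_case(coarse_params):
    return make_phantom(coarse_params, 11)


@pytest.fixture(scope="session")
def small_library(default_params):
    """Three-atlas library plus two targets on the default grid."""
    atlases, targets = make_cohort(default_params, 3, 2, master_seed=1)
    lib = AtlasLibrary([Atlas(a.case_id, a.volume, a.label) for a in atlases])
    return lib, atlases, targets


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
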