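import dataclasses

import numpy as np
import pytest

from repli3d import VoxelGrid, make_nucleus
from repli3d.presets import structural_preset


@pytest.fixture(scope="session")
def fast_early_preset():
    """Half-resolution early-S preset for quick generator tests."""
    return dataclasses.replace(structural_preset("E"), coupling=0.8, com_displacement_um=0.27).scaled(2)


@pytest.fixture(scope="session")
def fast_early_nucleus(fast_early_preset):
    return make_nucleus(fast_early_preset, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_grid():
    data = np.arange(2 * 3 * 4, dtype=float).reshape(2, 3, 4)
    return VoxelGrid(data, (0.2, 0.07, 0.07))
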