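import numpy as np
import pytest

from jpresskit.spins import builtin_systems
from jpresskit.simulator import AcquisitionGrid, simulate_basis


@pytest.fixture(scope="session")
def small_grid():
    """8 echoes x 512 points spanning 35-315 ms: the scaled acquisition."""
    return AcquisitionGrid(n_te=8, te_values=0.035 + 0.040 * np.arange(8),
                           n_points=512)


@pytest.fixture(scope="session")
def systems():
    return builtin_systems()


@pytest.fixture(scope="session")
def smoke_basis(small_grid, systems):
    """Unit-concentration basis for NAA, Cr, GABA and water."""
    return simulate_basis([systems[m] for m in ["NAA", "Cr", "GABA", "water"]],
                          small_grid)
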