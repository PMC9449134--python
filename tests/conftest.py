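import numpy as np
import pytest

from invabc.config import PhenotypeParams, SimulationConfig
from invabc.lattice import LatticeState


def state_from_sites(lattice_edge: int, sites: dict, rng_seed: int = 0
                     ) -> LatticeState:
    """Build a LatticeState with cells at explicit sites.

    ``sites`` maps (x, y, z) -> clone label ("A" or "B").
    """
    L = lattice_edge
    grid = np.zeros((L, L, L), dtype=np.int8)
    idx = np.full((L, L, L), -1, dtype=np.int32)
    pos = np.zeros((2, L ** 3, 3), dtype=np.int32)
    counts = np.zeros(2, dtype=np.int64)
    for site, clone in sites.items():
        c = {"A": 0, "B": 1}[clone]
        j = counts[c]
        pos[c, j] = site
        idx[site] = j
        grid[site] = c + 1
        counts[c] = j + 1
    return LatticeState(grid=grid, idx=idx, pos=pos, counts=counts,
                        rng_seed=rng_seed)


@pytest.fixture
def single_cell_state():
    """One clone-A cell in the middle of a 9^3 lattice."""
    return state_from_sites(9, {(4, 4, 4): "A"})


@pytest.fixture
def two_cell_state():
    """The two-clone propensity fixture: one A cell and one B cell."""
    return state_from_sites(9, {(2, 4, 4): "A", (6, 4, 4): "B"})


@pytest.fixture
def two_cell_params():
    """A(p=1, m=1), B(p=2, m=0): total propensity 1+1+0.1 + 2+0+0.2 = 4.3."""
    return (PhenotypeParams(1.0, 1.0), PhenotypeParams(2.0, 0.0))


@pytest.fixture
def tiny_config():
    return SimulationConfig(lattice_edge=24, seed_radius=3, seeding_ratio=1.0,
                            end_time=1.0, snapshot_interval=1.0, rng_seed=42)
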