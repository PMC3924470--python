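import numpy as np
import pytest

from arealrisk.areal_core import AreaLattice, SpatialWeights, build_contiguity
from arealrisk.standardization import CountTable, compute_expected
from arealrisk.synthetic_data import generate, grid_lattice, shenzhen_like


@pytest.fixture(scope="session")
def grid3() -> AreaLattice:
    return grid_lattice(3, 3)


@pytest.fixture(scope="session")
def grid3_rook(grid3) -> SpatialWeights:
    return build_contiguity(grid3, rule="rook")


@pytest.fixture(scope="session")
def grid3_queen(grid3) -> SpatialWeights:
    return build_contiguity(grid3, rule="queen")


@pytest.fixture(scope="session")
def shenzhen_dataset():
    """One seeded 57-area synthetic dataset with expected counts filled."""
    lattice, weights, table, truth = generate(shenzhen_like(seed=3))
    return lattice, weights, compute_expected(table), truth


def make_table(observed, population) -> CountTable:
    observed = np.asarray(observed, dtype=float)
    population = np.asarray(population, dtype=float)
    ids = [f"A{k:03d}" for k in range(observed.size)]
    return CountTable(area_ids=ids, observed=observed, population=population)
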