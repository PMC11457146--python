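import numpy as np
import pytest

from alkatherm.isomers import enumerate_isomers
from alkatherm.molecule import Molecule, name_to_molecule

from oracles import random_alkane_tree


@pytest.fixture(scope="session")
def c10_isomers():
    return enumerate_isomers(10)

@pytest.fixture(scope="session")
def all_isomers_to_c8():
    return {n: enumerate_isomers(n) for n in range(1, 9)}


@pytest.fixture(scope="session")
def n_c14():
    return name_to_molecule("n-C14")


@pytest.fixture(scope="session")
def random_trees():
    """500 random degree-<=4 trees with 1..12 sites (seeded)."""
    rng = np.random.default_rng(20240923)
    trees = []
    for _ in range(500):
        n = int(rng.integers(1, 13))
        edges = random_alkane_tree(rng, n)
        trees.append(Molecule(edges, n_atoms=n))
    return trees


@pytest.fixture(scope="session")
def synthetic_noiseless():
    from alkatherm.dataset import generate_synthetic_table

    return generate_synthetic_table(
        seed=11, n_max=7, temperatures=(0.0, 300.0, 400.0, 500.0, 600.0)
    )


@pytest.fixture(scope="session")
def synthetic_noisy():
    from alkatherm.dataset import generate_synthetic_table

    return generate_synthetic_table(
        seed=12,
        n_max=7,
        temperatures=(0.0, 300.0, 400.0, 500.0, 600.0),
        sigma=0.3,
    )
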