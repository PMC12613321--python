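import numpy as np
import pytest

from rigidpress.chem_core import Molecule
from rigidpress.fixtures import ToyMoleculeSpec, make_toy_molecule, single_sphere
from rigidpress.generation import GenerationConfig, generate_pool


@pytest.fixture(scope="session")
def rod3():
    """Three-atom C-O-N rod, 1.5 A spacing."""
    return make_toy_molecule(ToyMoleculeSpec(n_atoms=3, shape="rod", seed=1))


@pytest.fixture(scope="session")
def diatomic():
    """Two-atom C-O rod (cheap pressing)."""
    return make_toy_molecule(ToyMoleculeSpec(n_atoms=2, shape="rod", seed=2))


@pytest.fixture(scope="session")
def sphere():
    return single_sphere("C")


@pytest.fixture(scope="session")
def water_like():
    """Bent H-O-H with one extra O acceptor site, exercises H-bond tagging."""
    return Molecule(
        ["O", "H", "H"],
        np.array([[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [-0.24, 0.93, 0.0]]),
        np.array([1.52, 1.20, 1.20]),
        name="water-like",
    )


@pytest.fixture(scope="session")
def small_pool(diatomic):
    """30 proximity-valid Z=2 structures across five space groups."""
    cfg = GenerationConfig(n_per_sg=6, rng_seed=42)
    return generate_pool(diatomic, 2, cfg)
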