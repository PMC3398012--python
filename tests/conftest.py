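import numpy as np
import pandas as pd
import pytest

from molconnect.chemgraph import Atom, Bond, MolecularGraph
from molconnect.curation import LabelledDataset
from molconnect.synthetic import gen_random_graphs, gen_two_endpoint_study


def path_graph(n: int) -> MolecularGraph:
    atoms = [Atom("C", 3 if i in (0, n - 1) else 2) for i in range(n)]
    if n == 1:
        atoms = [Atom("C", 4)]
    return MolecularGraph(atoms=atoms,
                          bonds=[Bond(i, i + 1, 1.0) for i in range(n - 1)])


def star_graph(leaves: int) -> MolecularGraph:
    atoms = [Atom("C", max(0, 4 - leaves))] + [Atom("C", 3)] * leaves
    return MolecularGraph(atoms=atoms,
                          bonds=[Bond(0, i + 1, 1.0) for i in range(leaves)])


def cycle_graph(n: int) -> MolecularGraph:
    atoms = [Atom("C", 2) for _ in range(n)]
    bonds = [Bond(i, (i + 1) % n, 1.0, in_ring=True) for i in range(n)]
    return MolecularGraph(atoms=atoms, bonds=bonds)


@pytest.fixture(scope="session")
def random_trees():
    return gen_random_graphs(60, n_range=(2, 12), cycle_prob=0.0, seed=11)


@pytest.fixture(scope="session")
def random_graphs_mixed():
    return gen_random_graphs(60, n_range=(3, 8), cycle_prob=0.4, seed=12)


@pytest.fixture(scope="session")
def small_study():
    """Scaled planted study for fast statistical tests."""
    return gen_two_endpoint_study(n_per_endpoint=150, p=40, n_common=8,
                                  n_unique_a=2, n_unique_b=2,
                                  effect_sd=1.5, noise_sd=0.5, seed=5)


def planted_dataset(n=120, p=6, n_informative=2, effect=1.5, seed=0,
                    endpoint="hia") -> LabelledDataset:
    """Simple additive planted-signal data set for classifier tests."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, p))
    lin = effect * x[:, :n_informative].sum(axis=1) / np.sqrt(n_informative)
    y = np.where(rng.random(n) < 1 / (1 + np.exp(-lin)), 1, -1)
    if np.unique(y).size < 2:
        y[0] = -y[0]
    frame = pd.DataFrame(x, columns=[f"d{i}" for i in range(p)])
    return LabelledDataset(frame, y, endpoint)
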