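import numpy as np
import pytest

from phyloassembly import read_newick
from phyloassembly.synthetic_data import simulate_experiment

CHERRY = "((A:1,B:1):1,C:2);"


@pytest.fixture
def cherry_tree():
    """Three-tip tree: d(A,B)=2, d(A,C)=d(B,C)=4."""
    return read_newick(CHERRY)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def experiment():
    """One paper-like synthetic experiment shared across tests (seed-fixed)."""
    return simulate_experiment(seed=42)


@pytest.fixture(scope="session")
def internal_pool(experiment):
    meta = experiment.species
    return frozenset(meta.loc[meta["pool"] == "internal", "species_id"])
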