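import warnings

import numpy as np
import pytest

from copyevol.simulate import (CloneSimConfig, FamilySimConfig,
                               simulate_clone_libraries, simulate_family)


@pytest.fixture(scope="session")
def small_family():
    """One small simulated family shared across tests (2 species)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        copies, truth, tree = simulate_family(
            FamilySimConfig(n_species=2, seed=11))
    return copies, truth, tree


@pytest.fixture(scope="session")
def small_libraries(small_family):
    copies, truth, _ = small_family
    libs, mapping = simulate_clone_libraries(
        copies, truth, CloneSimConfig(clones_per_sample=60, seed=5))
    return libs, mapping


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
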