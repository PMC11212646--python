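import numpy as np
import pytest

from diallelkit import CrossMeanTable, SimTruth, simulate


@pytest.fixture(scope="session")
def default_truth():
    """Paper-scale generating truth: 8 parents, 3 reps, grain-yield scale."""
    return SimTruth.random(seed=20240901)

@pytest.fixture(scope="session")
def sim_data(default_truth):
    return simulate(default_truth)


@pytest.fixture(scope="session")
def sim_means(sim_data):
    from diallelkit import entry_means

    return entry_means(sim_data, "GY")


def random_means(p=4, seed=0, trait="y"):
    """Unstructured random p x p mean table (no model assumed)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(50.0, 10.0, (p, p))
    return CrossMeanTable(trait=trait, parents=tuple(f"P{i+1}" for i in range(p)), x=x)
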