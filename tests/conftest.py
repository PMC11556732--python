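import numpy as np
import pytest

from coraltrace.synth import SimulationConfig, simulate_isotopologue_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small null dataset (no treatment effects) with full control design."""
    cfg = SimulationConfig(seed=20240611, n_metabolites=8)
    return simulate_isotopologue_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
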