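import numpy as np
import pytest

from coevoppi import SimulationConfig, simulate_dataset, simulate_species_tree


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete simulated dataset (15 species, 3 pos + 5 neg)."""
    cfg = SimulationConfig(
        n_species=15,
        n_pos_pairs=3,
        n_neg_pairs=5,
        loss_rate=0.08,
        seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def species_tree_12():
    return simulate_species_tree(12, seed=7)
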