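import numpy as np
import pytest

from recland.features import WindowGrid
from recland.synth import SyntheticScenario, generate_bundle


@pytest.fixture
def grid_small():
    """Four full 100 kb windows plus one 50 kb partial window."""
    return WindowGrid(chrom_length=450_000, window_size=100_000, chrom="chr01")


@pytest.fixture(scope="session")
def bundle_small():
    """A small noiseless synthetic chromosome shared across read-only tests."""
    scenario = SyntheticScenario(
        chrom_length=5_000_000, window_size=100_000, seed=7, noise_sd=0.0
    )
    return scenario, generate_bundle(scenario)


@pytest.fixture(scope="session")
def bundle_noisy():
    scenario = SyntheticScenario(
        chrom_length=8_000_000, window_size=100_000, seed=21, noise_sd=0.05
    )
    return scenario, generate_bundle(scenario)
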