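import numpy as np
import pytest

from damidtile import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config():
    """A fast-but-complete study: 400 kb genome, 40 genes, 20 planted peaks."""
    return SimulationConfig(
        seed=11, n_chroms=2, chrom_length_bp=200_000, n_genes=40,
        n_peaks_a=8, n_peaks_b=6, n_peaks_c=6,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def default_study():
    """The default stated world (2 Mb, 200 genes, 100 planted peaks)."""
    return simulate_study(SimulationConfig(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
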