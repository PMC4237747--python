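import numpy as np
import pytest

from photoclines.synthdata import (
    SimulationConfig,
    make_populations,
    simulate_frequencies,
)


@pytest.fixture(scope="session")
def small_sim():
    """10 populations x 300 SNPs, 5% clinal; shared across fast tests."""
    cfg = SimulationConfig(n_pops=10, n_snps=300, frac_selected=0.05, seed=11)
    pops, env = make_populations(cfg)
    table, truth = simulate_frequencies(cfg, pops, env)
    return cfg, pops, env, table, truth


@pytest.fixture(scope="session")
def neutral_sim():
    """52 populations x 2000 neutral SNPs for calibration-style tests."""
    cfg = SimulationConfig(n_pops=52, n_snps=2000, frac_selected=0.0, seed=5)
    pops, env = make_populations(cfg)
    table, truth = simulate_frequencies(cfg, pops, env)
    assert not truth.any()
    return cfg, pops, env, table


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
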