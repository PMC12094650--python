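import numpy as np
import pytest

from polygxe import (
    SimulationConfig,
    estimate_ld,
    simulate_panel,
    simulate_sumstats,
)


@pytest.fixture(scope="session")
def sim2000():
    """Moderate-size simulated panel + summary statistics shared by the
    posterior-mean weight tests."""
    cfg = SimulationConfig(M=2000, n_ref=1500, block_size=40, master_seed=11)
    panel = simulate_panel(cfg)
    sumstats, truth = simulate_sumstats(panel, cfg)
    return cfg, panel, sumstats, truth


@pytest.fixture(scope="session")
def ld2000(sim2000):
    _, panel, _, _ = sim2000
    return estimate_ld(panel, shrinkage=0.01)


@pytest.fixture(scope="session")
def small_sim():
    """Tiny panel for fast unit tests."""
    cfg = SimulationConfig(M=120, n_ref=400, block_size=20, master_seed=5)
    panel = simulate_panel(cfg)
    sumstats, truth = simulate_sumstats(panel, cfg)
    return cfg, panel, sumstats, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
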