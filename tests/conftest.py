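import pytest

from proxiglyc.synthetic import SimConfig, generate_experiment


@pytest.fixture(scope="session")
def default_experiment():
    """One default-scale synthetic labelling experiment (seed 7)."""
    return generate_experiment(SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_experiment():
    """A small experiment for fast structural tests: tails are still
    detectable because k_min-sized spiking is preserved."""
    cfg = SimConfig(n_proteins=600, n_spiked=30, seed=11)
    return generate_experiment(cfg)
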