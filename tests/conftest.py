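import numpy as np
import pytest

from clonescan import simulate as sim


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated clone pair shared by read-only tests."""
    cfg = sim.SimulationConfig(n_genes=25, seed=11, n_contaminants=6, n_rrna=3)
    ancestral, clone_a, clone_b, truth = sim.simulate_transcriptomes(cfg)
    return cfg, ancestral, clone_a, clone_b, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
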