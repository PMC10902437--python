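import numpy as np
import pytest

from ldrefine import simpop


@pytest.fixture(scope="session")
def small_sim():
    """A small but non-trivial simulated instance shared across tests."""
    cfg = simpop.SimulationConfig(
        chromosome_length=400_000,
        n_scaffolds=6,
        n_samples=25,
        n_founders=5,
        n_sites=900,
        recomb_rate=1e-5,
        seed=11,
    )
    truth, panel = simpop.simulate_truth(cfg)
    return cfg, truth, panel


@pytest.fixture(scope="session")
def sim_files(small_sim, tmp_path_factory):
    cfg, truth, panel = small_sim
    outdir = tmp_path_factory.mktemp("simdata")
    files = simpop.emit_dataset(truth, panel, outdir, seed=cfg.seed)
    return truth, panel, files


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
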