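import numpy as np
import pytest

from deepdel.config import SimulationConfig
from deepdel.simulate import simulate_split


@pytest.fixture(scope="session")
def tiny_sim(tmp_path_factory):
    """A small simulated genome shared by caller/simulator/CLI tests:
    60 kb, 4 deletions of 60-800 bp, 20x coverage, short reads."""
    cfg = SimulationConfig(genome_length=60_000, n_deletions=4,
                           deletion_size_range=(60, 800), coverage=20.0,
                           read_length_range=(500, 4000),
                           noise_deletion_rate=5e-4, seed=11)
    return simulate_split(cfg, tmp_path_factory.mktemp("tiny_sim"),
                          name="tiny", T=50), cfg


@pytest.fixture(scope="session")
def end2end_metrics(tmp_path_factory):
    """Full synthetic pipeline on the easy fixture (trains the network)."""
    from deepdel.pipeline import run_end2end

    out = tmp_path_factory.mktemp("e2e")
    return run_end2end(seed=1, out_dir=out), out
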