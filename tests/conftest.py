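import numpy as np
import pandas as pd
import pytest

from epifunnel.synthetic import SimConfig, generate_genome, generate_wgbs, simulate_all


@pytest.fixture(scope="session")
def small_cfg():
    """A compact study: 24 genes (6 planted), 60 patients."""
    return SimConfig(seed=11, n_genes=24, n_planted=6, n_patients=60)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return simulate_all(small_cfg)


@pytest.fixture(scope="session")
def small_genome(small_sim):
    return small_sim["genome"], small_sim["genes"], small_sim["true_cgis"], small_sim["truth"]


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
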