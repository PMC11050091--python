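import numpy as np
import pytest

from tetrags import SimConfig, simulate_population


@pytest.fixture(scope="session")
def pop50():
    """Small tetraploid population: 50 genotypes x 300 loci, mean depth 60."""
    cfg = SimConfig(n_genotypes=50, n_loci=300, seed=3, bias_log_sd=0.2)
    gt, rc, ann = simulate_population(cfg)
    return cfg, gt, rc, ann


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
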