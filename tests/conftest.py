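import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from bsascan import SimConfig, simulate_f2_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """One modest simulated experiment shared by read-only tests."""
    cfg = SimConfig(
        n_f2=200,
        bulk_size=30,
        n_chromosomes=3,
        chrom_length_bp=40_000_000,
        n_loci=900,
        causal_chrom="chr02",
        causal_pos_bp=20_000_000,
        seed=11,
    )
    table, truth = simulate_f2_experiment(cfg)
    return cfg, table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
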