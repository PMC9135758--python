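import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from lesionlineage.genome import make_genome
from lesionlineage.synthetic_data import SimConfig, simulate_pair


@pytest.fixture(scope="session")
def small_layout():
    """1 chromosome x 10 Mb at 10 kb bins (1,000 bins)."""
    return make_genome(1, 10_000_000, 10_000)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale-in-miniature study conditions for fast tests."""
    return SimConfig(
        n_chrom=1,
        chrom_len=10_000_000,
        n_het_sites=800,
        n_shared_events=4,
        n_private_events=4,
        event_len_bins=(30, 80),
    )


@pytest.fixture(scope="session")
def small_pair(small_config):
    """One simulated parallel pair at the miniature scale."""
    return simulate_pair("parallel", 7, small_config)


def assert_monotone(trace, rel=1e-6):
    trace = np.asarray(trace)
    slack = rel * (np.abs(trace[:-1]) + 1.0)
    assert np.all(np.diff(trace) >= -slack), f"log-likelihood decreased: {trace}"
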