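import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import assortlif as al

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return al.NeuronParams()


@pytest.fixture(scope="session")
def dist_a2():
    return al.truncated_powerlaw(-2.0, 10, 500)


@pytest.fixture(scope="session")
def small_net():
    """Small configuration-model network with a narrow degree range."""
    dist = al.truncated_powerlaw(-2.0, 3, 12)
    seq = al.sample_degree_sequence(dist, 300, 7)
    return al.configuration_model(seq, 8)


@pytest.fixture(scope="session")
def net_a2_10k(dist_a2):
    """Uncorrelated alpha=-2 network at desk scale (N=1e4), seed 0."""
    seq = al.sample_degree_sequence(dist_a2, 10_000, 0)
    return al.configuration_model(seq, 1)


@pytest.fixture(scope="session")
def net_a2_10k_assortative(net_a2_10k):
    net, _ = al.metropolis_rewire(
        net_a2_10k,
        "assortative",
        g=1.0,
        n_attempts=600 * net_a2_10k.n_edges,
        seed=2,
        plateau_tol=1e-4,
        plateau_window=20,
    )
    return net


@pytest.fixture(scope="session")
def net_a2_10k_disassortative(net_a2_10k):
    net, _ = al.metropolis_rewire(
        net_a2_10k,
        "disassortative",
        g=1.0,
        n_attempts=600 * net_a2_10k.n_edges,
        seed=3,
        plateau_tol=1e-4,
        plateau_window=20,
    )
    return net
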