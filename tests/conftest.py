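import numpy as np
import pytest

from ssanet.lif import LIFParams, simulate
from ssanet.topology import NetworkSpec, make_network


@pytest.fixture(scope="session")
def small_unclustered():
    """N=500 unclustered reference network, shared across tests."""
    spec = NetworkSpec(kind="unclustered", N=500, c=10, seed=11)
    W, part = make_network(spec)
    return spec, W, part


@pytest.fixture(scope="session")
def small_clustered():
    """N=500, c=10, R_EE=3.4 clustered network."""
    spec = NetworkSpec(kind="clustered_prob", N=500, c=10, R_EE=3.4, seed=11)
    W, part = make_network(spec)
    return spec, W, part


@pytest.fixture(scope="session")
def small_clustered_raster(small_clustered):
    _, W, part = small_clustered
    raster = simulate(W, LIFParams(duration=5.0, seed=5))
    return raster, part


def poisson_raster(rates_hz, duration_ms, N, seed=0):
    """Homogeneous Poisson raster; rates_hz per neuron (scalar or array)."""
    rng = np.random.default_rng(seed)
    rates = np.broadcast_to(np.asarray(rates_hz, float), (N,))
    neurons, times = [], []
    for i, r in enumerate(rates):
        n = rng.poisson(r * duration_ms / 1000.0)
        t = rng.uniform(0, duration_ms, n)
        neurons.append(np.full(n, i))
        times.append(t)
    neurons = np.concatenate(neurons).astype(int)
    times = np.concatenate(times)
    order = np.argsort(times)
    from ssanet.lif import SpikeRaster
    return SpikeRaster(neurons=neurons[order], times=times[order], N=N,
                       duration_ms=duration_ms)
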