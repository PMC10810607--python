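import numpy as np
import pytest
from hypothesis import settings

import timescale_reservoir as tr

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def dmft_s1_g15():
    """Converged mean-field solution for the all-s=1, g=1.5 network.

    Shared across tests: its HWHM timescale tau1 and noise strength D
    parameterize the colored-noise probe theory.
    """
    return tr.iterate_dmft(tr.SelfCouplingSpec.degenerate(1.0), 1.5, seed=4)


@pytest.fixture(scope="session")
def small_rate_net():
    spec = tr.SelfCouplingSpec.two_populations(0.8, 3.2, 0.5)
    return tr.build_network(300, 2.0, spec, seed=3)


@pytest.fixture(scope="session")
def spiking_dwell_data():
    """Pooled (self-coupling, mean activation time) pairs from clustered
    N=2000 networks, 20 s epochs, 10 realizations."""
    from timescale_reservoir import spiking

    rows = []
    for seed in range(10):
        net = spiking.build_spiking_network(
            spiking.SpikingParams(N=2000), seed=100 + seed
        )
        spk = spiking.simulate_lif(net, 20000.0, seed=200 + seed)
        for a in spiking.assembly_activation_times(spk, net):
            if not a.flagged:
                rows.append((a.s_E, a.mean_T))
    s = np.array([r[0] for r in rows])
    T = np.array([r[1] for r in rows])
    return s, T


@pytest.fixture(scope="session")
def clustered_net():
    """N=2000 clustered spiking network (shared; building is cheap, the
    weight matrix is reused by several structural tests)."""
    from timescale_reservoir import spiking

    return spiking.build_spiking_network(
        spiking.SpikingParams(N=2000), seed=100
    )
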