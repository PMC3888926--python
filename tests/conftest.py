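import numpy as np
import pytest

from hebbca import ArchitectureParams, DynamicsParams, Simulator, build_network


@pytest.fixture(scope="session")
def small_arch() -> ArchitectureParams:
    """A small architecture used across unit tests (fast to build)."""
    return ArchitectureParams(rows=8, cols=8, n_exc=5, n_inh=3,
                              p0_within=0.5, p0_between=0.5)


@pytest.fixture()
def small_net(small_arch):
    # function-scoped: several tests mutate weights via plasticity
    return build_network("full", small_arch, seed=7)


@pytest.fixture()
def quiet_dynamics() -> DynamicsParams:
    """Noise-free dynamics with no baseline drive (rest is exactly zero)."""
    return DynamicsParams(k2=0.0, Vb=0.0)


@pytest.fixture()
def small_sim(small_net, quiet_dynamics) -> Simulator:
    return Simulator(small_net, quiet_dynamics, seed=3)


def make_profile(rng: np.random.Generator, n_patterns: int, n_cells: int):
    """Random probe-response profile in [0, 1]."""
    return rng.random((n_patterns, n_cells))
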