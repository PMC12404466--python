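import numpy as np
import pytest

import fiberlight as fl

#: scaled-down grid used for the expensive convergence checks
SMALL = dict(xymax=200, zmax=200, dxy=10, dz=10)


@pytest.fixture(scope="session")
def default_config():
    return fl.config_from_dict()


@pytest.fixture(scope="session")
def small_config():
    return fl.config_from_dict(SMALL)


@pytest.fixture(scope="session")
def small_run(small_config):
    return fl.simulate_fiber(small_config)


@pytest.fixture(scope="session")
def default_run(default_config):
    """Full default-parametrization simulation (700 × 700 μm, Δ = 5 μm)."""
    return fl.simulate_fiber(default_config)


@pytest.fixture(scope="session")
def small_cone(small_config):
    """Point-emitter cone (pencil field + angular convolution) on the
    scaled-down grid, shared by disk-convolution tests."""
    from fiberlight.fiber import build_cone
    return build_cone(small_config)


@pytest.fixture(scope="session")
def tau_report(small_config):
    from fiberlight.oracles import dense_tau_oracle
    return dense_tau_oracle(small_config, 10_000)


@pytest.fixture(scope="session")
def angular_reports(small_config):
    """Angular-convergence reports at 2x and 4x refinement."""
    from fiberlight.oracles import dense_angular_oracle
    return {f: dense_angular_oracle(small_config, f) for f in (2, 4)}
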