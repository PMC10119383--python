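import numpy as np
import pytest

from polychamber import (DepolymerizationParams, KineticParams, LatticeSpec,
                         SimConfig, TransportParams)


@pytest.fixture
def small_spec():
    return LatticeSpec(n_rows=10, n_cols=10)


@pytest.fixture
def tiny_config():
    """A fast chamber configuration for functional tests (seconds, not
    minutes): small lattice, short run."""
    return SimConfig(
        lattice=LatticeSpec(n_rows=12, n_cols=12),
        transport=TransportParams(D_P=50.0, D_E=200.0, D_O=500.0),
        depoly=DepolymerizationParams(k_cat=30.0, K_P=0.05),
        kinetics=KineticParams(K_enz=0.3, mu_max=0.3, K_m=0.01, Y=0.5),
        rho=0.2,
        duration=1.0,
        dt=0.01,
        seed=42,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
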