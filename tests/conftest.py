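import numpy as np
import pytest

from dyadsync.synthetic import (CouplingConfig, DesignConfig, default_kernels,
                                generate_dataset, make_schedule)

#: Coupling config with every idiosyncratic noise source silenced, so the
#: kappa=1 / lag=0 observer is an exact copy of the demonstrator.
QUIET = dict(lag=0.0, spontaneous_rate=0.0, noise_sd=0.0, amp_jitter_sd=0.0,
             spont_jitter_sd=0.0, latency_jitter_sd=0.0,
             latency_jitter_min=0.0, lag_warp_sd=0.0, drift_sd=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def design8():
    """Default trial structure, generated directly at the 8 Hz analysis rate."""
    return DesignConfig(sample_rate=8, seed=0)


@pytest.fixture
def schedule(rng):
    return make_schedule(DesignConfig(), 1, rng)


@pytest.fixture
def kernels():
    return default_kernels()


@pytest.fixture(scope="session")
def small_dataset():
    """Four dyads, two blocks, 8 Hz — shared across read-only tests."""
    design = DesignConfig(n_dyads=4, n_blocks=2, sample_rate=8, seed=3)
    return generate_dataset(design, seed=3)


def quiet_coupling(**overrides) -> CouplingConfig:
    kw = dict(QUIET)
    kw.update(overrides)
    return CouplingConfig(**kw)
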