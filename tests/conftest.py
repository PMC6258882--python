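import numpy as np
import pytest

from mwfpipe.epg import EchoTrainSpec, epg_echo_amplitudes_batch
from mwfpipe.spectrum import BasisCache, FitConfig, make_t2_grid


@pytest.fixture(scope="session")
def train():
    return EchoTrainSpec(echo_spacing=0.010, n_echoes=32, repetition_time=1.0)


@pytest.fixture(scope="session")
def grid():
    return make_t2_grid(0.015, 2.0, 40)


@pytest.fixture(scope="session")
def fit_cfg():
    return FitConfig()


@pytest.fixture(scope="session")
def basis_cache(grid, train):
    return BasisCache(grid, train)


@pytest.fixture(scope="session")
def two_pool_curve(train):
    """Factory for noiseless two-pool decay curves at a given flip angle."""

    def make(angle, mwf=0.2, t2_myelin=0.020, t2_ie=0.070, t1=1.0):
        short = epg_echo_amplitudes_batch(t2_myelin, t1, angle, train)
        long_ = epg_echo_amplitudes_batch(t2_ie, t1, angle, train)
        return mwf * short + (1.0 - mwf) * long_

    return make
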