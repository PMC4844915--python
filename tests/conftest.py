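import numpy as np
import pytest

import dynpac as dp


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def coupled_fixture():
    """Strong theta->gamma coupled pair, 20 s at 256 Hz, ground-truth phase."""
    ep = dp.CouplingEpoch(0.0, 20.0, f_phase=6.0, f_amp=40.0, chi=0.8)
    a, b, phase = dp.simulate_coupled_pair(ep, 20.0, rate_hz=256.0,
                                           noise_sd=0.5, seed=7,
                                           return_phase=True)
    return ep, a, b, phase


@pytest.fixture(scope="session")
def coupled_tvpac(coupled_fixture):
    """Prominent-mode series of the coupled fixture (directed pair 0->1)."""
    _, a, b, _ = coupled_fixture
    rec = dp.Recording(np.column_stack([a, b]), 256.0)
    return dp.build_tvpac(
        rec, pairs=[(0, 1)],
        surrogate=dp.SurrogateConfig(n_surrogates=200, seed=7))
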