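import numpy as np
import pytest

import wmosc


@pytest.fixture(scope="session")
def small_sweep():
    """One reduced network sweep shared across experiment/acceptance tests:
    the full 24-level grid, both memory conditions, 12 s per run (10 s kept
    after the transient)."""
    cfg = wmosc.SweepConfig(duration_ms=12_000.0)
    df, store = wmosc.run_network_sweep(cfg, seed=2024)
    return cfg, df, store


@pytest.fixture(scope="session")
def quiet_network():
    """Noise-free, uncoupled single-pair network parameters for closed-form
    LIF checks."""
    par, drv, noi = wmosc.default_network_params()
    from dataclasses import replace
    par = replace(par, N=1, w_ee=0.0, w_ii=0.0, w_ie=0.0, w_ei=0.0)
    noi = replace(noi, sigma_w=0.0, sigma_c=0.0)
    return par, drv, noi


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
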