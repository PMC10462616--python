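import numpy as np
import pytest

import hipponav as h
from hipponav.preprocess import extract_features


@pytest.fixture(scope="session")
def coupled_run():
    """A compact speed-coupled session with its features, shared by tests."""
    cfg = h.SimConfig(duration_s=240.0, n_channels=6, g_theta=0.5,
                      g_gamma=0.5, seed=7)
    session, trace = h.generate_session(cfg)
    table = extract_features(session, trace)
    return cfg, session, trace, table


@pytest.fixture(scope="session")
def null_run():
    """Same-sized session with coupling gains zero (no speed information)."""
    cfg = h.SimConfig(duration_s=240.0, n_channels=6, g_theta=0.0,
                      g_gamma=0.0, seed=7)
    session, trace = h.generate_session(cfg)
    table = extract_features(session, trace)
    return cfg, session, trace, table


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
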