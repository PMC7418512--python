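import numpy as np
import pytest

import tcrspec as ts


@pytest.fixture(scope="session")
def small_screen():
    """A small simulated screen with doublets, reused across tests."""
    cfg = ts.ScreenSimConfig(
        n_clonotypes=80,
        n_antigens=3,
        n_donors=2,
        n_nc=3,
        n_surface=4,
        clone_size=("geometric", 0.5),
        max_clone_size=3,
        doublet_rate=0.05,
        seed=42,
    )
    return ts.simulate_screen(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
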